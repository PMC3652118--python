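# The twenty published example rules of the risk model, verbatim.
# These rows are a locked fixture: the generated full rule base must agree
# with every one of them.  Labels use the printed synonyms (little, not
# common, "null") which the variable alias maps resolve.
rules:
  - {if: {age: young, sexual_onset: young, partners: little, pregnancies: "null", first_pregnancy_age: young, std_history: "no", lesions: "no"}, then: negative}
  - {if: {age: young, sexual_onset: young, partners: little, pregnancies: "null", first_pregnancy_age: young, std_history: "no", lesions: "yes"}, then: negative}
  - {if: {age: young, sexual_onset: young, partners: little, pregnancies: "null", first_pregnancy_age: young, std_history: "yes", lesions: "no"}, then: negative}
  - {if: {age: young, sexual_onset: young, partners: little, pregnancies: "null", first_pregnancy_age: young, std_history: "yes", lesions: "yes"}, then: negative}
  - {if: {age: young, sexual_onset: young, partners: many, pregnancies: "null", first_pregnancy_age: young, std_history: "no", lesions: "no"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: many, pregnancies: "null", first_pregnancy_age: young, std_history: "no", lesions: "yes"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: many, pregnancies: "null", first_pregnancy_age: young, std_history: "yes", lesions: "no"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: many, pregnancies: "null", first_pregnancy_age: young, std_history: "yes", lesions: "yes"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: not common, pregnancies: "null", first_pregnancy_age: young, std_history: "no", lesions: "no"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: not common, pregnancies: "null", first_pregnancy_age: young, std_history: "no", lesions: "yes"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: not common, pregnancies: "null", first_pregnancy_age: young, std_history: "yes", lesions: "no"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: not common, pregnancies: "null", first_pregnancy_age: young, std_history: "yes", lesions: "yes"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: little, pregnancies: little, first_pregnancy_age: adult, std_history: "no", lesions: "no"}, then: negative}
  - {if: {age: young, sexual_onset: young, partners: little, pregnancies: little, first_pregnancy_age: adult, std_history: "no", lesions: "yes"}, then: negative}
  - {if: {age: young, sexual_onset: young, partners: little, pregnancies: little, first_pregnancy_age: adult, std_history: "yes", lesions: "no"}, then: negative}
  - {if: {age: young, sexual_onset: young, partners: little, pregnancies: little, first_pregnancy_age: adult, std_history: "yes", lesions: "yes"}, then: negative}
  - {if: {age: young, sexual_onset: young, partners: many, pregnancies: little, first_pregnancy_age: adult, std_history: "no", lesions: "no"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: many, pregnancies: little, first_pregnancy_age: adult, std_history: "no", lesions: "yes"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: many, pregnancies: little, first_pregnancy_age: adult, std_history: "yes", lesions: "no"}, then: positive}
  - {if: {age: young, sexual_onset: young, partners: many, pregnancies: little, first_pregnancy_age: adult, std_history: "yes", lesions: "yes"}, then: positive}
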