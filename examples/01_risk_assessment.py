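"""Score clinical-background records on the fuzzy risk model.

Builds the shipped seven-variable risk model (972-combination rule base
generated from the severity policy, pinned to the published example rows)
and scores four patient records.  The crisp score lives on the risk
universe [0.5, 2.5]: values near 1 mean negative risk, near 2 positive.
"""

import cervidx as cx

model = cx.build_risk_model()

records = {
    "case 1 (47y, onset 23, 2 partners, 1 pregnancy at 27)":
        cx.ClinicalRecord(age=47, ivsa=23, ps=2, ng=1, pg=27, ets=False, le=False),
    "case 5 (43y, onset 16, 1 partner, 7 pregnancies, first at 28)":
        cx.ClinicalRecord(age=43, ivsa=16, ps=1, ng=7, pg=28, ets=False, le=False),
    "case 8 (50y, onset 19, 3 partners, 7 pregnancies, lesions found)":
        cx.ClinicalRecord(age=50, ivsa=19, ps=3, ng=7, pg=20, ets=False, le=True),
    "young, many partners (16y, onset 16, 7 partners, nulliparous)":
        cx.ClinicalRecord(age=16, ivsa=16, ps=7, ng=0, pg=None, ets=False, le=False),
}

for description, record in records.items():
    result = cx.assess_risk(record, model)
    print(f"{description}\n  -> risk score {result.score:.3f}, label {result.label} "
          f"({result.n_fired} rules fired)")

print("\nA negative label means the clinical background alone shows no risk "
      "of cervical neoplasia; the score feeds the injury-resolution model.")
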