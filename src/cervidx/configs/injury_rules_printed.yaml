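# The five published example rules of the injury-resolution model, verbatim.
# Locked fixture for the generated 108-rule base.
rules:
  - {if: {nucleus_area: small, staining: light,  eccentricity: regular, nucleoli: "null", risk: negative}, then: normal}
  - {if: {nucleus_area: small, staining: medium, eccentricity: regular, nucleoli: "null", risk: negative}, then: normal}
  - {if: {nucleus_area: small, staining: dark,   eccentricity: regular, nucleoli: "null", risk: negative}, then: normal}
  - {if: {nucleus_area: small, staining: light,  eccentricity: regular, nucleoli: few,    risk: negative}, then: normal}
  - {if: {nucleus_area: small, staining: medium, eccentricity: regular, nucleoli: few,    risk: negative}, then: normal}
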