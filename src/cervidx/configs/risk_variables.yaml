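# Clinical-background "risk" model: seven input variables and the risk output.
# Intervals are the specialist-elicited breakpoints of the published system.
# The output universe follows the variant on which risk feeds the injury model
# directly; the narrow [0, 1.5] variant is kept under output_presets.
name: risk
inputs:
  - name: age
    universe: [10, 90]
    sets:
      - {label: young,  shape: trapezoid, params: [10, 15, 18, 22]}
      - {label: adult,  shape: trapezoid, params: [18, 22, 34, 45]}
      - {label: mature, shape: trapezoid, params: [38, 44, 90, 90]}
  - name: sexual_onset
    universe: [10, 90]
    sets:
      - {label: young,  shape: trapezoid, params: [10, 15, 18, 22]}
      - {label: adult,  shape: trapezoid, params: [18, 22, 34, 45]}
      - {label: mature, shape: trapezoid, params: [38, 44, 90, 90]}
  - name: partners
    universe: [0, 20]
    sets:
      - {label: few,     shape: trapezoid, params: [0, 2, 3, 4]}
      - {label: many,    shape: trapezoid, params: [3, 5, 9, 10]}
      - {label: unusual, shape: trapezoid, params: [9, 15, 20, 20]}
    aliases: {"little": few, "not common": unusual, "not_common": unusual}
  - name: pregnancies
    universe: [0, 18]
    sets:
      - {label: "null", shape: triangle,  params: [0, 0, 0.5]}
      - {label: few,    shape: triangle,  params: [0.51, 4, 8]}
      - {label: many,   shape: trapezoid, params: [7, 8, 18, 18]}
    aliases: {"little": few, "none": "null"}
  - name: first_pregnancy_age
    universe: [10, 90]
    sets:
      - {label: young,  shape: trapezoid, params: [10, 15, 18, 22]}
      - {label: adult,  shape: trapezoid, params: [18, 22, 34, 45]}
      - {label: mature, shape: trapezoid, params: [38, 44, 90, 90]}
  - name: std_history
    universe: [0, 1.5]
    sets:
      - {label: "no",  shape: triangle, params: [0, 0, 0.5]}
      - {label: "yes", shape: triangle, params: [0.51, 1, 1.5]}
  - name: lesions
    universe: [0, 1.5]
    sets:
      - {label: "no",  shape: triangle, params: [0, 0, 0.5]}
      - {label: "yes", shape: triangle, params: [0.51, 1, 1.5]}
output:
  name: risk
  universe: [0.5, 2.5]
  sets:
    - {label: negative, shape: triangle, params: [0.5, 1, 1.5]}
    - {label: positive, shape: triangle, params: [1.51, 2, 2.5]}
output_presets:
  narrow:
    name: risk
    universe: [0, 1.5]
    sets:
      - {label: negative, shape: triangle, params: [0, 0, 0.5]}
      - {label: positive, shape: triangle, params: [0.51, 1, 1.5]}
engine:
  and_op: min
  defuzz_mode: exact
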