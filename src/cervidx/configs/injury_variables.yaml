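# "Injury resolution" model: four morphometric inputs from the cytology
# image, the crisp risk score, and the three-way lesion output.
# dn = mean nucleus area (px), tn = mean staining (inverted-grayscale scale),
# hn = mean eccentricity, pn = total nucleolus count.
name: injury_resolution
inputs:
  - name: nucleus_area            # dn
    universe: [0, 25000]
    sets:
      - {label: small,  shape: trapezoid, params: [0, 0, 5000, 6000]}
      - {label: medium, shape: trapezoid, params: [4500, 6800, 9000, 10000]}
      - {label: large,  shape: trapezoid, params: [9000, 9900, 25000, 25000]}
  - name: staining                # tn
    universe: [50, 150]
    sets:
      - {label: clear, shape: trapezoid, params: [50, 50, 80, 82]}
      - {label: media, shape: trapezoid, params: [79, 82, 87, 92]}
      - {label: dark,  shape: trapezoid, params: [87, 92, 150, 150]}
    aliases: {"light": clear, "medium": media}
  - name: eccentricity            # hn
    universe: [0, 1]
    sets:
      - {label: regular,   shape: trapezoid, params: [0.5, 0.5, 0.74, 0.77]}
      - {label: irregular, shape: trapezoid, params: [0.75, 0.8, 1, 1]}
  - name: nucleoli                # pn
    universe: [0, 150]
    sets:
      - {label: "null", shape: triangle,  params: [0, 0, 2]}
      - {label: few,    shape: trapezoid, params: [2, 9, 20, 30]}
      - {label: many,   shape: trapezoid, params: [24, 40, 150, 150]}
  - name: risk
    universe: [0.5, 2.5]
    sets:
      - {label: negative, shape: triangle, params: [0.5, 1, 1.5]}
      - {label: positive, shape: triangle, params: [1.51, 2, 2.5]}
output:
  name: lesion
  universe: [0, 100]
  sets:
    - {label: normal,   shape: trapezoid, params: [0, 0, 31, 41]}
    - {label: agc,      shape: trapezoid, params: [31, 41, 58, 68]}
    - {label: positive, shape: trapezoid, params: [58, 68, 100, 100]}
  aliases: {"positive to malignity": positive, "positive_to_malignity": positive, "no alterations": normal}
engine:
  and_op: min
  defuzz_mode: exact
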