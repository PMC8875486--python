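input_sets:
  low:
    kind: trapezoidal
    breakpoints:
    - 0.0
    - 0.0
    - 0.2
    - 0.55
  high:
    kind: trapezoidal
    breakpoints:
    - 0.45
    - 0.8
    - 1.0
    - 1.0
output_sets:
  rejected:
    kind: triangular
    breakpoints:
    - 0.0
    - 0.125
    - 0.25
  doubtful:
    kind: triangular
    breakpoints:
    - 0.25
    - 0.375
    - 0.5
  acceptable:
    kind: triangular
    breakpoints:
    - 0.5
    - 0.625
    - 0.75
  confident:
    kind: triangular
    breakpoints:
    - 0.75
    - 0.875
    - 1.0
rules:
- if:
  - low
  - low
  - low
  then: rejected
- if:
  - low
  - low
  - high
  then: doubtful
- if:
  - low
  - high
  - low
  then: doubtful
- if:
  - low
  - high
  - high
  then: acceptable
- if:
  - high
  - low
  - low
  then: doubtful
- if:
  - high
  - low
  - high
  then: acceptable
- if:
  - high
  - high
  - low
  then: acceptable
- if:
  - high
  - high
  - high
  then: confident
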