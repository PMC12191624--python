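# Standard network fixtures: three-variable teaching structures and the
# four-variable diamond used in the three experimental conditions.
# Link format: [source, target, polarity]; polarity is generative|inhibitory.
# exo_tied: whether non-root variables share one exogenous weight (the
# three-variable fixtures default to untied per-effect weights).
networks:
  common_cause:
    variables: [C, EA, EB]
    links:
      - [C, EA, generative]
      - [C, EB, generative]
    exo_tied: false
  chain:
    variables: [X, Y, Z]
    links:
      - [X, Y, generative]
      - [Y, Z, generative]
    exo_tied: false
  common_effect:
    variables: [CA, CB, E]
    links:
      - [CA, E, generative]
      - [CB, E, generative]
    exo_tied: false
  common_cause_geninh:
    variables: [C, EA, EB]
    links:
      - [C, EA, generative]
      - [C, EB, inhibitory]
    exo_tied: false
  diamond_generative:
    variables: [X, YA, YB, Z]
    links:
      - [X, YA, generative]
      - [X, YB, generative]
      - [YA, Z, generative]
      - [YB, Z, generative]
    exo_tied: true
  diamond_ya_inhibitory:
    variables: [X, YA, YB, Z]
    links:
      - [X, YA, generative]
      - [X, YB, generative]
      - [YA, Z, inhibitory]
      - [YB, Z, generative]
    exo_tied: true
  diamond_yb_inhibitory:
    variables: [X, YA, YB, Z]
    links:
      - [X, YA, generative]
      - [X, YB, generative]
      - [YA, Z, generative]
      - [YB, Z, inhibitory]
    exo_tied: true
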