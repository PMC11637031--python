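{
  "description": "One-shot pilot: final best fitness on the 10-D sphere objective (optimum at the hypercube center), P=10, T=50, seeds 0-9 passed as rng. Committed verbatim; the per-algorithm competence bound rounds the pilot maximum up to one coarse step and is not revised.",
  "dim": 10,
  "P": 10,
  "T": 50,
  "seeds": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9],
  "finals": {
    "sho": [0.435, 0.491, 0.384, 0.348, 0.489, 0.418, 0.317, 0.412, 0.401, 0.343],
    "sca": [0.517, 0.428, 0.374, 0.35, 0.398, 0.444, 0.148, 0.293, 0.411, 0.481],
    "shosca": [0.00523, 0.0265, 0.00962, 0.0172, 0.0136, 0.0232, 0.00307, 0.00822, 0.0096, 0.0208],
    "shosca-motor": [0.512, 0.499, 0.398, 0.291, 0.533, 0.425, 0.316, 0.548, 0.418, 0.362],
    "shosca-breeding": [0.295, 0.424, 0.148, 0.35, 0.498, 0.478, 0.354, 0.316, 0.448, 0.481]
  },
  "bounds": {
    "sho": 0.55,
    "sca": 0.55,
    "shosca": 0.03,
    "shosca-motor": 0.6,
    "shosca-breeding": 0.55
  }
}
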