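"""Spectral-library search with dot-product and entropy similarity.

Run:  python examples/library_search.py
"""

from flavotier import (
    PipelineConfig,
    SimulationConfig,
    build_quasi_library,
    cosine_score,
    entropy_score,
    search_level2a,
    simulate_spectrum,
)

# The 39-compound (quasi) reference library, and a noisy simulated
# spectrum of one member (3 mDa fragment jitter, 5 decoy peaks).
entries = build_quasi_library()
library = [record for record, _ in entries]
template = next(t for _, t in entries if t.name == "quercetin")
query = simulate_spectrum(template, SimulationConfig(seed=11))

cfg = PipelineConfig()  # identification score cutoff 80 %
hits = search_level2a(query, library, cfg)
print("library hits (score >= 80 %):")
for hit in hits:
    print(f"  {hit.record.name:20s} {hit.score.percent:5.1f} %")

# Entropy similarity is an alternative scorer over the same alignment.
reference = next(r for r in library if r.name == "quercetin").spectrum
print(f"\ncosine : {cosine_score(query, reference).percent:.1f} %")
print(f"entropy: {entropy_score(query, reference).percent:.1f} %")
print("Scores are percentages of maximal spectral agreement; a hit above "
      "90 % would be promoted to a quasi-reference record.")
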