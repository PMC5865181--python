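#!/usr/bin/env python
"""Generate the synthetic decade of GO/GOA versions the study runs on.

Writes a 12-version OBO/GAF archive (2004..2015 analogue) with six planted
enriched branches introduced at staggered versions, plus one gene signature
per branch, under results/synthetic/. Later steps read these files back, so
every parser in the pipeline is exercised on real artefacts.
"""

from pathlib import Path

from ontodrift.simulate import (
    EvolutionConfig,
    simulate_signatures,
    simulate_versions,
    write_fixtures,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
CONFIG = EvolutionConfig(n_versions=12, rng_seed=2015)


def main() -> None:
    series = simulate_versions(CONFIG)
    signatures = simulate_signatures(CONFIG)
    paths = write_fixtures(series, signatures, OUT, CONFIG)
    first, last = series[0][0], series[-1][0]
    print(f"wrote {len(paths['obo'])} versions to {OUT}")
    print(
        f"terms {len(first.active_terms())} -> {len(last.active_terms())} "
        f"({len(last.active_terms()) / len(first.active_terms()):.1f}-fold)"
    )
    print(
        f"annotations {len(series[0][1])} -> {len(series[-1][1])} "
        f"({len(series[-1][1]) / len(series[0][1]):.1f}-fold)"
    )
    print(f"signatures: {[s.name for s in signatures]}")


if __name__ == "__main__":
    main()
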