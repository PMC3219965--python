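#!/usr/bin/env python
"""Hi-C tag-pair interaction counts per supranucleosomal domain and band class.

Simulates two Hi-C-style experiments in which Giemsa-negative (gene-rich)
bands favor interactions around domain III while Giemsa-positive bands are
flat, then runs the full processing chain: tag-to-restriction-site mapping,
intra-band filtering, the >= 4-pair multiplicity filter, domain binning,
per-class normalization and per-domain t-tests.  Writes results/hic/.
"""

from pathlib import Path

from helixchrom import simulate_hic_tag_pairs
from helixchrom.enrichment import hic_domain_comparison, map_tag_pairs_to_fragments
from helixchrom.simulate import make_bands, make_fragments

OUT = Path(__file__).resolve().parent.parent / "results" / "hic"
SEED = 2024
WEIGHTS = {
    "gneg": [0.14, 0.12, 0.30, 0.10, 0.20, 0.14],  # domain-III (and V) excess
    "gpos": [1 / 6] * 6,
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bands = make_bands()
    fragments = make_fragments()
    experiments = {}
    for i in range(2):
        tags = simulate_hic_tag_pairs(
            bands, fragments, WEIGHTS, n_pairs=1500, seed=SEED + i
        )
        positioned = map_tag_pairs_to_fragments(tags, fragments)
        experiments[f"experiment_{i + 1}"] = positioned
        print(f"experiment_{i + 1}: {len(tags)} tag pairs, "
              f"{len(positioned)} positioned")

    result = hic_domain_comparison(experiments, bands, min_multiplicity=4)
    result["summary"].to_csv(OUT / "hic_domain_summary.tsv", sep="\t")
    for name, table in result["per_experiment"].items():
        table.to_csv(OUT / f"domains_{name}.tsv", sep="\t")

    print("normalized interaction fractions (mean over experiments):")
    for dom, row in result["summary"].iterrows():
        print(f"  {dom}: G-neg {row['gneg_mean']:.3f} vs "
              f"G-pos {row['gpos_mean']:.3f}  (p = {row.get('p', float('nan')):.2g}) "
              f"{row.get('stars', '')}")
    d3 = result["summary"].loc["D.III"]
    if d3["gneg_mean"] > d3["gpos_mean"] and d3["p"] < 0.05:
        print("=> gene-rich (G-neg) bands favor ~90-kb (domain III) interactions, "
              "as planted")


if __name__ == "__main__":
    main()
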