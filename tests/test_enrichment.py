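"""Co-expression selection, domain counting, randomization, Hi-C comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from helixchrom.enrichment import (
    STUDENT_T_29_95,
    classify_band,
    conserved_element_domain_counts,
    enrichment_report,
    hic_domain_comparison,
    map_tag_pairs_to_fragments,
    randomized_baseline,
    select_coexpressed_genes,
)
from helixchrom.simulate import (
    make_bands,
    make_fragments,
    simulate_coexpression_fixture,
    simulate_hic_tag_pairs,
)

TISSUES = [f"tissue_{t:02d}" for t in range(20)]


def gene_table(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "strand", "housekeeping"]
    )


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def test_selection_threshold_semantics(rng):
    base = rng.normal(0, 1, 20)
    noise = rng.normal(0, 1, 20)

    def blend(target_r):
        # construct a vector with an exact target correlation against base
        b = (base - base.mean()) / base.std()
        n = (noise - np.polyfit(b, noise, 1)[0] * b - noise.mean())
        n = n / n.std()
        return target_r * b + np.sqrt(1 - target_r**2) * n

    expr = pd.DataFrame(
        {
            "identical_a": base,
            "identical_b": base,
            "weak": blend(0.79),
            "opposite": -base,
        },
        index=TISSUES,
    ).T
    genes = gene_table(
        [
            ("identical_a", "chr1", 1_000_000, "+", 0),
            ("identical_b", "chr1", 1_100_000, "+", 0),  # 100 kb: r = 1, selected
            ("weak", "chr1", 1_150_000, "+", 0),  # r = 0.79 vs both: excluded
            ("opposite", "chr1", 1_200_000, "+", 0),  # r = -1: selected
        ]
    )
    pairs = select_coexpressed_genes(expr, genes)
    selected = set(pairs.attrs["selected_genes"])
    assert {"identical_a", "identical_b", "opposite"} <= selected
    assert "weak" not in selected
    rs = pairs.set_index(["gene_a", "gene_b"])["r"]
    assert rs.loc[("identical_a", "identical_b")] == pytest.approx(1.0)


def test_housekeeping_and_distance_filters(rng):
    base = rng.normal(0, 1, 20)
    expr = pd.DataFrame(
        {"hk_a": base, "hk_b": base, "far_a": base, "far_b": base}, index=TISSUES
    ).T
    genes = gene_table(
        [
            ("hk_a", "chr1", 1_000_000, "+", 1),
            ("hk_b", "chr1", 1_050_000, "+", 1),
            ("far_a", "chr2", 1_000_000, "+", 0),
            ("far_b", "chr2", 1_500_000, "+", 0),  # 500 kb > 400 kb: excluded
        ]
    )
    pairs = select_coexpressed_genes(expr, genes)
    assert pairs.empty
    assert pairs.attrs["rejects"]["housekeeping"] == 2


def test_min_tissue_requirement(rng):
    base = rng.normal(0, 1, 20)
    sparse = base.copy()
    sparse[10:] = np.nan  # only 10 shared tissues
    expr = pd.DataFrame({"a": base, "b": sparse}, index=TISSUES).T
    genes = gene_table([("a", "chr1", 0, "+", 0), ("b", "chr1", 50_000, "+", 0)])
    pairs = select_coexpressed_genes(expr, genes)
    assert pairs.empty
    assert pairs.attrs["rejects"]["few_tissues"] == 1


def test_planted_clusters_are_recovered_exactly():
    fx = simulate_coexpression_fixture(n_genes=100, n_clusters=8, seed=10)
    pairs = select_coexpressed_genes(fx.expression, fx.genes)
    assert set(pairs.attrs["selected_genes"]) == set(fx.truth["cluster_genes"])


# ---------------------------------------------------------------------------
# conserved-element domain counts
# ---------------------------------------------------------------------------

def element(chrom, mid, length=200):
    return {"chrom": chrom, "start": int(mid - length / 2), "end": int(mid + length / 2)}


def test_element_binning_and_promoter_rule():
    genes = gene_table([("g", "chr1", 1_000_000, "+", 0)])
    tus = pd.DataFrame(
        [{"chrom": "chr1", "start": 1_000_000, "end": 1_010_000, "gene_id": "g"}]
    )
    elements = pd.DataFrame(
        [
            element("chr1", 1_090_000),  # 90 kb downstream: D.III
            element("chr1", 1_002_000),  # inside the transcription unit: excluded
            element("chr1", 998_000),    # 2 kb upstream: promoter rule, excluded
            element("chr1", 960_000),    # 40 kb upstream: D.II
        ]
    )
    rel = conserved_element_domain_counts(genes, elements, tus)
    assert rel["D.III"] == pytest.approx(0.5)
    assert rel["D.II"] == pytest.approx(0.5)
    assert rel.attrs["rejects"]["in_transcription_unit"] == 1
    assert rel.attrs["rejects"]["promoter_proximal"] == 1
    assert rel.sum() == pytest.approx(1.0)


def test_biased_fixture_counts_recover_placement():
    bias = [0.05, 0.05, 0.4, 0.1, 0.3, 0.1]
    fx = simulate_coexpression_fixture(
        n_genes=150, n_clusters=12, domain_bias=bias, elements_per_gene=40, seed=11
    )
    primary = fx.genes[fx.genes["gene_id"].isin(fx.truth["primary_genes"])]
    rel = conserved_element_domain_counts(
        primary, fx.conserved_elements, fx.transcription_units, all_tss=fx.genes
    )
    assert rel["D.III"] == pytest.approx(0.4, abs=0.06)
    assert rel["D.V"] == pytest.approx(0.3, abs=0.06)


# ---------------------------------------------------------------------------
# randomization baseline and report
# ---------------------------------------------------------------------------

def test_confidence_halfwidth_formula():
    fx = simulate_coexpression_fixture(n_genes=80, n_clusters=5, seed=12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        baseline = randomized_baseline(
            fx.genes, fx.conserved_elements, fx.transcription_units,
            n_genes=30, n_reps=30, seed=12,
        )
    expected = STUDENT_T_29_95 * baseline.table["sigma"] / np.sqrt(30)
    np.testing.assert_allclose(baseline.table["E"], expected, rtol=1e-12)
    assert STUDENT_T_29_95 * 1.0 / np.sqrt(30) == pytest.approx(0.3724, abs=1e-4)
    assert baseline.n_randomizations == 30
    assert "shapiro_p" in baseline.table.columns


def test_degenerate_randomization_has_zero_halfwidth():
    # one eligible draw composition -> all randomizations identical -> sigma = 0
    fx = simulate_coexpression_fixture(n_genes=24, n_clusters=2, seed=13)
    pool = fx.genes[~fx.genes["housekeeping"].astype(bool)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        baseline = randomized_baseline(
            fx.genes, fx.conserved_elements, fx.transcription_units,
            n_genes=len(pool), n_reps=5, seed=0,
        )
    assert np.allclose(baseline.table["E"], 0.0)


def test_observed_equal_to_baseline_is_null():
    fx = simulate_coexpression_fixture(n_genes=80, n_clusters=5, seed=14)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        baseline = randomized_baseline(
            fx.genes, fx.conserved_elements, fx.transcription_units,
            n_genes=30, n_reps=20, seed=14,
        )
    report = enrichment_report(baseline.table["mu"], baseline)
    assert np.allclose(report["pct_dev"], 0.0)
    assert (report["p"] > 0.95).all()


def test_enrichment_sign_recovery_round_trip():
    bias = [0.05, 0.05, 0.45, 0.05, 0.3, 0.1]
    hits = 0
    for seed in range(5):
        fx = simulate_coexpression_fixture(
            n_genes=100, n_clusters=10, domain_bias=bias, seed=100 + seed
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs = select_coexpressed_genes(fx.expression, fx.genes)
            selected = fx.genes[fx.genes["gene_id"].isin(pairs.attrs["selected_genes"])]
            observed = conserved_element_domain_counts(
                selected, fx.conserved_elements, fx.transcription_units,
                all_tss=fx.genes,
            )
            baseline = randomized_baseline(
                fx.genes, fx.conserved_elements, fx.transcription_units,
                n_genes=40, n_reps=30, seed=100 + seed,
            )
            report = enrichment_report(observed, baseline)
        hits += report.loc["D.III", "pct_dev"] > 0
    assert hits == 5


# ---------------------------------------------------------------------------
# tag-pair mapping
# ---------------------------------------------------------------------------

def test_direction_convention():
    frags = pd.DataFrame(
        [
            {"fragment_id": 1, "chrom": "chr1", "start": 1000, "end": 5000},
            {"fragment_id": 2, "chrom": "chr1", "start": 8000, "end": 12000},
        ]
    )
    pairs = pd.DataFrame(
        [
            {"chrom": "chr1", "fragment_1": 1, "direction_1": 0,
             "fragment_2": 2, "direction_2": 1},
            {"chrom": "chr1", "fragment_1": 1, "direction_1": 1,
             "fragment_2": 2, "direction_2": 0},
            {"chrom": "chr1", "fragment_1": 99, "direction_1": 0,
             "fragment_2": 2, "direction_2": 0},  # unknown fragment
        ]
    )
    positioned = map_tag_pairs_to_fragments(pairs, frags)
    assert len(positioned) == 2
    assert positioned.attrs["rejects"]["unknown_fragment"] == 1
    # direction 0 -> 3' end (end coordinate); direction 1 -> 5' end (start)
    assert positioned.loc[0, "position_1"] == 5000
    assert positioned.loc[0, "position_2"] == 8000
    assert positioned.loc[0, "separation_bp"] == 3000
    assert positioned.loc[1, "separation_bp"] == 11000  # 1000 vs 12000


def test_band_classification():
    assert classify_band("gneg") == "gneg"
    assert classify_band("gpos50") == "gpos"
    assert classify_band("gpos100") == "gpos"
    assert classify_band("gpos25") is None
    assert classify_band("acen") is None


def test_hic_round_trip_detects_planted_domain_bias():
    bands, frags = make_bands(), make_fragments()
    weights = {"gneg": [0.05, 0.05, 0.6, 0.1, 0.1, 0.1], "gpos": [1 / 6] * 6}
    experiments = {}
    for i in range(2):
        tags = simulate_hic_tag_pairs(bands, frags, weights, n_pairs=800, seed=30 + i)
        experiments[f"exp{i}"] = map_tag_pairs_to_fragments(tags, frags)
    result = hic_domain_comparison(experiments, bands)
    summary = result["summary"]
    assert summary.loc["D.III", "gneg_mean"] > summary.loc["D.III", "gpos_mean"]
    assert summary.loc["D.III", "p"] < 0.05
    for name, table in result["per_experiment"].items():
        np.testing.assert_allclose(table.sum(axis=0), 1.0, rtol=1e-9)


def test_multiplicity_filter_drops_rare_interactions():
    bands, frags = make_bands(), make_fragments()
    tags = simulate_hic_tag_pairs(
        bands, frags, {"gneg": [1 / 6] * 6, "gpos": [1 / 6] * 6},
        n_pairs=400, keep_fraction=0.5, seed=31,
    )
    positioned = map_tag_pairs_to_fragments(tags, frags)
    strict = hic_domain_comparison({"e": positioned}, bands, min_multiplicity=4)
    loose = hic_domain_comparison({"e": positioned}, bands, min_multiplicity=1)
    # relative counts still normalize to 1 in both cases
    for result in (strict, loose):
        for table in result["per_experiment"].values():
            sums = table.sum(axis=0)
            np.testing.assert_allclose(sums[sums > 0], 1.0, rtol=1e-9)
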