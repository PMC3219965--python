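"""Domain enrichment analyses around co-expressed genes and in Hi-C tag pairs.

Two analyses share the supranucleosomal domain scheme of the modulation scan:

1. Conserved-sequence enrichment: genes with strongly correlated (|r| >= 0.8)
   tissue expression and a partner within 400 kb are selected (housekeeping
   genes excluded first); TSS-to-conserved-element separation distances up to
   250 kb are binned into domains D.I-D.VI and compared against a
   randomization baseline (30 draws of 130 genes; 95% CI half-width
   E = t sigma / sqrt(N) with t = 2.04, Shapiro-Wilk normality check per
   domain).

2. Hi-C tag-pair domain counting: intra-band pairs only, unique fragment
   pairs with multiplicity >= 4, separations binned per domain, normalized
   per Giemsa band class, classes compared per domain by t-test across
   experiments.

All coordinates are 0-based half-open bp internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, shapiro, ttest_1samp, ttest_ind, ttest_rel

from .modulation import DEFAULT_DOMAINS, DomainScheme, significance_stars

__all__ = [
    "STUDENT_T_29_95",
    "classify_band",
    "select_coexpressed_genes",
    "conserved_element_domain_counts",
    "RandomizationSummary",
    "randomized_baseline",
    "enrichment_report",
    "map_tag_pairs_to_fragments",
    "hic_domain_comparison",
]

#: Student t multiplier for a 95% CI at 29 degrees of freedom, kept as the
#: fixed constant of the reference procedure.
STUDENT_T_29_95 = 2.04

_GPOS_STAINS = {"gpos50", "gpos75", "gpos100"}
_EXCLUDED_STAINS = {"acen", "gvar", "stalk"}


def classify_band(stain: str) -> str | None:
    """Map a cytoband stain value to 'gneg' / 'gpos' (>= gpos50) or None.

    Centromeric/variable/stalk bands and weak gpos25 staining are excluded
    from both classes.
    """
    if stain == "gneg":
        return "gneg"
    if stain in _GPOS_STAINS:
        return "gpos"
    return None


# ---------------------------------------------------------------------------
# co-expressed gene selection
# ---------------------------------------------------------------------------

def select_coexpressed_genes(
    expression: pd.DataFrame,
    genes: pd.DataFrame,
    r_abs_min: float = 0.8,
    min_tissues: int = 15,
    max_sep_kb: float = 400.0,
) -> pd.DataFrame:
    """Gene pairs with |Pearson r| >= r_abs_min over >= min_tissues shared tissues.

    ``expression``: genes x tissues matrix (NaN = not measured).  Housekeeping
    genes are removed before pairing; candidate pairs are same-chromosome TSS
    pairs closer than ``max_sep_kb``.  Returns the retained pairs; the selected
    gene set is ``attrs["selected_genes"]`` and filter tallies are in
    ``attrs["rejects"]``.
    """
    rejects = {"housekeeping": int(genes["housekeeping"].astype(bool).sum())}
    pool = genes[~genes["housekeeping"].astype(bool)].copy()

    missing = [g for g in pool["gene_id"] if g not in expression.index]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) lack expression vectors; skipped")
    rejects["no_expression"] = len(missing)
    pool = pool[pool["gene_id"].isin(expression.index)]

    max_sep_bp = max_sep_kb * 1000.0
    pairs = []
    n_candidates = n_few_tissues = n_low_r = 0
    for chrom, group in pool.groupby("chrom"):
        group = group.sort_values("tss").reset_index(drop=True)
        tss = group["tss"].to_numpy(dtype=float)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                sep = tss[j] - tss[i]
                if sep >= max_sep_bp:
                    break  # sorted: no later j can be closer
                n_candidates += 1
                va = expression.loc[group.loc[i, "gene_id"]].to_numpy(dtype=float)
                vb = expression.loc[group.loc[j, "gene_id"]].to_numpy(dtype=float)
                shared = np.isfinite(va) & np.isfinite(vb)
                if shared.sum() < min_tissues:
                    n_few_tissues += 1
                    continue
                r = float(pearsonr(va[shared], vb[shared]).statistic)
                if abs(r) < r_abs_min:
                    n_low_r += 1
                    continue
                pairs.append(
                    {
                        "gene_a": group.loc[i, "gene_id"],
                        "gene_b": group.loc[j, "gene_id"],
                        "r": r,
                        "n_tissues": int(shared.sum()),
                        "separation_bp": float(sep),
                        "chrom": chrom,
                    }
                )
    out = pd.DataFrame(
        pairs, columns=["gene_a", "gene_b", "r", "n_tissues", "separation_bp", "chrom"]
    )
    rejects.update({"candidate_pairs": n_candidates, "few_tissues": n_few_tissues,
                    "low_correlation": n_low_r})
    out.attrs["selected_genes"] = sorted(set(out["gene_a"]) | set(out["gene_b"]))
    out.attrs["rejects"] = rejects
    return out


def conserved_element_domain_counts(
    selected_genes: pd.DataFrame,
    conserved_elements: pd.DataFrame,
    transcription_units: pd.DataFrame,
    all_tss: pd.DataFrame | None = None,
    scheme: DomainScheme = DEFAULT_DOMAINS,
    promoter_kb: float = 3.0,
    max_sep_kb: float = 250.0,
) -> pd.Series:
    """Relative counts of TSS-to-element separations per domain (sum to 1).

    Elements inside any transcription unit, or with midpoint within
    ``promoter_kb`` of any TSS (``all_tss`` defaults to the selected genes),
    are excluded.  Distances use the element midpoint.  Filter tallies are in
    ``attrs["rejects"]``.
    """
    if all_tss is None:
        all_tss = selected_genes
    mid = (
        conserved_elements["start"].to_numpy(dtype=float)
        + conserved_elements["end"].to_numpy(dtype=float)
    ) / 2.0
    chroms = conserved_elements["chrom"].to_numpy()

    keep = np.ones(len(mid), dtype=bool)
    in_tu = np.zeros(len(mid), dtype=bool)
    near_tss = np.zeros(len(mid), dtype=bool)
    for chrom in np.unique(chroms):
        cmask = chroms == chrom
        tu = transcription_units[transcription_units["chrom"] == chrom]
        for _, row in tu.iterrows():
            inside = cmask & (mid >= row["start"]) & (mid < row["end"])
            in_tu |= inside
        tss = all_tss[all_tss["chrom"] == chrom]["tss"].to_numpy(dtype=float)
        if len(tss):
            dmin = np.min(
                np.abs(mid[cmask, None] - tss[None, :]), axis=1
            )
            sub = np.zeros(len(mid), dtype=bool)
            sub[np.nonzero(cmask)[0]] = dmin < promoter_kb * 1000.0
            near_tss |= sub
    keep &= ~(in_tu | near_tss)

    boundaries_bp = np.asarray(scheme.boundaries) * 1000.0
    counts = pd.Series(0.0, index=list(scheme.labels))
    n_pairs = 0
    for _, gene in selected_genes.iterrows():
        cmask = keep & (chroms == gene["chrom"])
        d = np.abs(mid[cmask] - gene["tss"])
        d = d[d < max_sep_kb * 1000.0]
        n_pairs += len(d)
        idx = np.searchsorted(boundaries_bp, d, side="right") - 1
        for i in range(len(scheme.labels)):
            counts.iloc[i] += int(np.sum(idx == i))
    total = counts.sum()
    rel = counts / total if total > 0 else counts
    rel.attrs["rejects"] = {
        "in_transcription_unit": int(in_tu.sum()),
        "promoter_proximal": int((near_tss & ~in_tu).sum()),
        "n_elements_kept": int(keep.sum()),
        "n_separations": n_pairs,
    }
    rel.attrs["n_separations"] = n_pairs
    return rel


# ---------------------------------------------------------------------------
# randomization baseline
# ---------------------------------------------------------------------------

@dataclass
class RandomizationSummary:
    """Per-domain randomization statistics with E = t sigma / sqrt(N)."""

    table: pd.DataFrame  # index = domains; columns mu, sigma, E, shapiro_p
    replicates: pd.DataFrame  # reps x domains relative counts
    n_randomizations: int
    t_multiplier: float
    seed: int

    def __post_init__(self):
        expected = self.t_multiplier * self.table["sigma"] / np.sqrt(self.n_randomizations)
        assert np.allclose(self.table["E"], expected)


def randomized_baseline(
    genes: pd.DataFrame,
    conserved_elements: pd.DataFrame,
    transcription_units: pd.DataFrame,
    n_genes: int = 130,
    n_reps: int = 30,
    seed: int = 0,
    scheme: DomainScheme = DEFAULT_DOMAINS,
    t_multiplier: float = STUDENT_T_29_95,
) -> RandomizationSummary:
    """Relative domain counts for random gene draws from the database."""
    pool = genes[~genes["housekeeping"].astype(bool)].reset_index(drop=True)
    if len(pool) < n_genes:
        raise ValueError(f"database holds {len(pool)} genes < n_genes = {n_genes}")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        draw = pool.iloc[rng.choice(len(pool), size=n_genes, replace=False)]
        rel = conserved_element_domain_counts(
            draw, conserved_elements, transcription_units, all_tss=genes, scheme=scheme
        )
        reps.append(rel)
    replicates = pd.DataFrame(reps).reset_index(drop=True)
    mu = replicates.mean(axis=0)
    sigma = replicates.std(axis=0, ddof=1)
    e = t_multiplier * sigma / np.sqrt(n_reps)
    shapiro_p = {}
    for dom in replicates.columns:
        vals = replicates[dom].to_numpy()
        if np.ptp(vals) == 0:
            shapiro_p[dom] = np.nan
        else:
            shapiro_p[dom] = float(shapiro(vals).pvalue)
            if shapiro_p[dom] < 0.05:
                warnings.warn(f"randomized counts in {dom} deviate from normality")
    table = pd.DataFrame(
        {"mu": mu, "sigma": sigma, "E": e, "shapiro_p": pd.Series(shapiro_p)}
    )
    return RandomizationSummary(
        table=table,
        replicates=replicates,
        n_randomizations=n_reps,
        t_multiplier=t_multiplier,
        seed=seed,
    )


def enrichment_report(observed: pd.Series, baseline: RandomizationSummary) -> pd.DataFrame:
    """Percent deviation of observed counts from the randomization mean.

    p-values are one-sample t-tests of the randomization distribution against
    the observed value, per domain.
    """
    rows = []
    for dom in baseline.table.index:
        mu = baseline.table.loc[dom, "mu"]
        obs = observed.get(dom, np.nan)
        if mu == 0 or not np.isfinite(mu):
            rows.append({"domain": dom, "observed": obs, "mu": mu, "pct_dev": np.nan,
                         "p": np.nan, "stars": "", "significant": False})
            continue
        pct = 100.0 * (obs - mu) / mu
        reps = baseline.replicates[dom].to_numpy()
        if np.ptp(reps) == 0:
            p = 0.0 if obs != mu else 1.0
        else:
            p = float(ttest_1samp(reps, obs).pvalue)
        rows.append(
            {
                "domain": dom,
                "observed": obs,
                "mu": mu,
                "E": baseline.table.loc[dom, "E"],
                "pct_dev": pct,
                "p": p,
                "stars": significance_stars(p),
                "significant": abs(obs - mu) > baseline.table.loc[dom, "E"],
            }
        )
    return pd.DataFrame(rows).set_index("domain")


# ---------------------------------------------------------------------------
# Hi-C tag pairs
# ---------------------------------------------------------------------------

def map_tag_pairs_to_fragments(
    tag_pairs: pd.DataFrame, fragments: pd.DataFrame
) -> pd.DataFrame:
    """Replace tag fragment references by restriction-site positions.

    Direction 0 -> the 3' end of the fragment (its ``end`` coordinate);
    direction 1 -> the 5' end (``start``).  Separation = |site1 - site2|.
    Unknown fragment ids are dropped and tallied in ``attrs["rejects"]``.
    """
    frag_idx = fragments.set_index(["chrom", "fragment_id"])
    starts = frag_idx["start"]
    ends = frag_idx["end"]

    def position(chrom, frag, direction):
        key = (chrom, frag)
        if key not in frag_idx.index:
            return np.nan
        return ends.loc[key] if direction == 0 else starts.loc[key]

    pos1 = np.array(
        [position(c, f, d) for c, f, d in
         zip(tag_pairs["chrom"], tag_pairs["fragment_1"], tag_pairs["direction_1"])],
        dtype=float,
    )
    pos2 = np.array(
        [position(c, f, d) for c, f, d in
         zip(tag_pairs["chrom"], tag_pairs["fragment_2"], tag_pairs["direction_2"])],
        dtype=float,
    )
    out = tag_pairs.copy()
    out["position_1"] = pos1
    out["position_2"] = pos2
    out["separation_bp"] = np.abs(pos1 - pos2)
    ok = np.isfinite(pos1) & np.isfinite(pos2)
    rejected = int((~ok).sum())
    out = out[ok].reset_index(drop=True)
    out.attrs["rejects"] = {"unknown_fragment": rejected}
    return out


def _assign_band(positions: pd.DataFrame, bands: pd.DataFrame) -> pd.Series:
    """Band index per pair if both ends fall in the same band, else -1."""
    band_id = np.full(len(positions), -1, dtype=int)
    for bi, band in bands.iterrows():
        inside = (
            (positions["chrom"] == band["chrom"]).to_numpy()
            & (positions["position_1"].to_numpy() >= band["start"])
            & (positions["position_1"].to_numpy() < band["end"])
            & (positions["position_2"].to_numpy() >= band["start"])
            & (positions["position_2"].to_numpy() < band["end"])
        )
        band_id[inside] = bi
    return pd.Series(band_id, index=positions.index)


def hic_domain_comparison(
    experiments: dict[str, pd.DataFrame],
    bands: pd.DataFrame,
    scheme: DomainScheme = DEFAULT_DOMAINS,
    min_multiplicity: int = 4,
    paired: bool = False,
) -> dict:
    """Normalized per-domain interaction counts per Giemsa class, with t-tests.

    ``experiments`` maps experiment name to positioned pairs (output of
    ``map_tag_pairs_to_fragments``).  Within each experiment and band class:
    keep intra-band pairs, collapse to unique fragment pairs with
    multiplicity >= ``min_multiplicity`` (tag directions ignored), bin the
    interaction separations into D.I-D.VI and normalize to the total over all
    six domains.  Classes are then compared per domain by a t-test across
    experiments (unpaired by default).
    """
    bands = bands.reset_index(drop=True).copy()
    bands["class"] = bands["gieStain"].map(classify_band)
    boundaries_bp = np.asarray(scheme.boundaries) * 1000.0

    per_exp = {}
    for name, pairs in experiments.items():
        pairs = pairs.copy()
        band_id = _assign_band(pairs, bands)
        pairs["band_id"] = band_id
        pairs = pairs[band_id >= 0]
        pairs["band_class"] = bands.loc[pairs["band_id"], "class"].to_numpy()
        pairs = pairs[pairs["band_class"].notna()]

        fractions = {}
        for cls, group in pairs.groupby("band_class"):
            inter = (
                group.groupby(["chrom", "fragment_1", "fragment_2"])
                .agg(multiplicity=("separation_bp", "size"),
                     separation_bp=("separation_bp", "first"))
                .reset_index()
            )
            inter = inter[inter["multiplicity"] >= min_multiplicity]
            idx = np.searchsorted(boundaries_bp, inter["separation_bp"].to_numpy(),
                                  side="right") - 1
            counts = np.array(
                [np.sum(idx == i) for i in range(len(scheme.labels))], dtype=float
            )
            total = counts.sum()
            fractions[cls] = counts / total if total > 0 else counts
        per_exp[name] = pd.DataFrame(fractions, index=list(scheme.labels))

    classes = sorted({c for table in per_exp.values() for c in table.columns})
    rows = []
    for i, dom in enumerate(scheme.labels):
        row = {"domain": dom}
        samples = {}
        for cls in classes:
            vals = np.array(
                [per_exp[name].loc[dom, cls] for name in per_exp if cls in per_exp[name]]
            )
            samples[cls] = vals
            row[f"{cls}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{cls}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
        if len(classes) == 2 and all(len(samples[c]) >= 2 for c in classes):
            a, b = samples[classes[0]], samples[classes[1]]
            if np.ptp(np.concatenate([a, b])) == 0:
                p = 1.0
            elif paired and len(a) == len(b):
                p = float(ttest_rel(a, b).pvalue)
            else:
                p = float(ttest_ind(a, b).pvalue)
            row["p"] = p
            row["stars"] = significance_stars(p)
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("domain")
    empty = [c for c in classes if all(
        (c not in per_exp[n].columns) or per_exp[n][c].sum() == 0 for n in per_exp
    )]
    return {"per_experiment": per_exp, "summary": summary, "classes": classes,
            "empty_classes": empty, "min_multiplicity": min_multiplicity}
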