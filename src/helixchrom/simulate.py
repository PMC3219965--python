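"""Synthetic generators for every input class the pipeline consumes.

All generators are pure functions of (design, seed): the same inputs always
produce byte-identical tables.  The contact-profile generator is the
generative twin of the polymer model -- frequencies are the model's
crosslinking frequency X(s) under multiplicative lognormal noise (3C
quantifications are positive with scale-proportional error), averaged over
replicate assays exactly as real 3C-qPCR points are.  The genomic generators
emulate an expression-database gene table with clustered co-expressed pairs,
conserved-element placement with a controllable domain bias, cytogenetic
bands, a restriction-fragment tiling, and genome-wide tag-pair sets with
per-domain interaction weights per band class.

Every generator returns its ground truth alongside the data so downstream
analyses can be tested closed-loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .modulation import DEFAULT_DOMAINS, DomainScheme
from .polymer import PolymerModel, crosslink_frequency

__all__ = [
    "SimulationDesign",
    "GenomicFixture",
    "simulate_contact_profile",
    "simulate_gene_desert_profile",
    "simulate_coexpression_fixture",
    "simulate_hic_tag_pairs",
    "make_bands",
    "make_fragments",
]

N_TISSUES = 20


@dataclass(frozen=True)
class SimulationDesign:
    """Study design for a synthetic 3C-qPCR contact profile.

    Defaults mirror the reference experiments: a handful of anchors read out
    at dozens of sites spanning 5-340 kb, three independent assays per point,
    and ~20% multiplicative noise (the scale of the observed SEM bars).
    """

    model: PolymerModel
    anchors: int = 5
    sites_per_anchor: int = 50
    s_range: tuple = (5.0, 340.0)
    noise_cv: float = 0.2
    n_assays: int = 3
    peaks: tuple = ()  # (separation_kb, fold) pairs
    locus: str = "synthetic"
    expression_class: str = "unknown"
    seed: int = 0


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_contact_profile(design: SimulationDesign) -> pd.DataFrame:
    """One row per (anchor, site): mean frequency, sem, n_assays.

    Separations are drawn per anchor from both sides of the anchor and
    pooled by absolute value, as in a real anchored 3C experiment.
    """
    lo, hi = design.s_range
    if lo <= 0:
        raise ValueError("s_range must exclude 0 (the model is singular there)")
    if hi <= lo:
        raise ValueError("s_range must be increasing")
    rng = np.random.default_rng(design.seed)
    rows = []
    for a in range(design.anchors):
        mag = rng.uniform(lo, hi, size=design.sites_per_anchor)
        side = rng.choice([-1.0, 1.0], size=design.sites_per_anchor)
        sep = np.abs(mag * side)  # pooled by absolute value
        base = crosslink_frequency(design.model, sep)
        for s_kb, fold in design.peaks:
            hit = np.abs(sep - s_kb) < 1e-9
            base = np.where(hit, base * fold, base)
        assays = base[:, None] * _lognormal_factors(
            rng, design.noise_cv, (design.sites_per_anchor, design.n_assays)
        )
        freq = assays.mean(axis=1)
        sem = (
            assays.std(axis=1, ddof=1) / math.sqrt(design.n_assays)
            if design.n_assays > 1
            else np.zeros_like(freq)
        )
        for i in range(design.sites_per_anchor):
            rows.append(
                {
                    "locus": design.locus,
                    "anchor_id": f"A{a}",
                    "site_id": f"A{a}_S{i}",
                    "separation_kb": float(sep[i]),
                    "frequency": float(freq[i]),
                    "sem": float(sem[i]),
                    "n_assays": design.n_assays,
                    "expression_class": design.expression_class,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "model": design.model.to_dict(),
        "noise_cv": design.noise_cv,
        "peaks": list(design.peaks),
        "seed": design.seed,
    }
    return df


#: steep short-range decay emulating a gene-desert locus: a very flexible
#: linear chain plus a small additive basal floor.
DESERT_MODEL = PolymerModel(family="linear", S=0.2, k=1.0, L=9.6)


def simulate_gene_desert_profile(
    design: SimulationDesign | None = None,
    floor_fraction: float = 0.005,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene-desert profile: collapse to near-basal collision levels by ~5-6 kb.

    Frequencies are X_linear(s; S = 0.2 kb) plus an additive floor at
    ``floor_fraction`` of X(1 kb), so there is no long-range modulation by
    construction.
    """
    if design is None:
        design = SimulationDesign(
            model=DESERT_MODEL,
            anchors=4,
            sites_per_anchor=40,
            s_range=(1.0, 250.0),
            locus="gene_desert",
            seed=0 if seed is None else seed,
        )
    lo, hi = design.s_range
    if lo <= 0:
        raise ValueError("s_range must exclude 0")
    rng = np.random.default_rng(design.seed)
    floor = floor_fraction * crosslink_frequency(design.model, 1.0)
    rows = []
    for a in range(design.anchors):
        sep = np.abs(
            rng.uniform(lo, hi, size=design.sites_per_anchor)
            * rng.choice([-1.0, 1.0], size=design.sites_per_anchor)
        )
        base = crosslink_frequency(design.model, sep) + floor
        assays = base[:, None] * _lognormal_factors(
            rng, design.noise_cv, (design.sites_per_anchor, design.n_assays)
        )
        freq = assays.mean(axis=1)
        sem = (
            assays.std(axis=1, ddof=1) / math.sqrt(design.n_assays)
            if design.n_assays > 1
            else np.zeros_like(freq)
        )
        for i in range(design.sites_per_anchor):
            rows.append(
                {
                    "locus": design.locus,
                    "anchor_id": f"A{a}",
                    "site_id": f"A{a}_S{i}",
                    "separation_kb": float(sep[i]),
                    "frequency": float(freq[i]),
                    "sem": float(sem[i]),
                    "n_assays": design.n_assays,
                    "expression_class": "unknown",
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "model": design.model.to_dict(),
        "floor": floor,
        "seed": design.seed,
    }
    return df


@dataclass
class GenomicFixture:
    """Bundle of genomic tables; coordinates are 0-based half-open bp."""

    genes: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    conserved_elements: pd.DataFrame | None = None
    transcription_units: pd.DataFrame | None = None
    bands: pd.DataFrame | None = None
    fragments: pd.DataFrame | None = None
    tag_pairs: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


def simulate_coexpression_fixture(
    n_genes: int = 200,
    n_clusters: int = 10,
    domain_bias: Sequence[float] | None = None,
    elements_per_gene: int = 20,
    seed: int = 0,
    scheme: DomainScheme = DEFAULT_DOMAINS,
) -> GenomicFixture:
    """Gene/expression/conserved-element fixture with planted structure.

    * ``n_clusters`` co-expressed gene pairs (within-pair expression
      correlation >= 0.9 by construction; alternate pairs anti-correlated).
    * Remaining genes: uncorrelated background plus a housekeeping-flagged
      subset (always excluded by the selection step).
    * Conserved intergenic elements are placed around cluster-gene TSSs at
      distances drawn from ``domain_bias`` over the six supranucleosomal
      domains (default uniform); decoy elements inside transcription units
      and promoters exercise the filters.
    """
    rng = np.random.default_rng(seed)
    if domain_bias is None:
        domain_bias = np.full(len(scheme.labels), 1.0 / len(scheme.labels))
    domain_bias = np.asarray(domain_bias, dtype=float)
    if len(domain_bias) != len(scheme.labels):
        raise ValueError("domain_bias needs one weight per domain")
    if not math.isclose(domain_bias.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("domain_bias must sum to 1")

    spacing = 1_000_000  # background genes sit > 400 kb apart
    gene_len = 10_000
    genes = []
    expr = {}
    cluster_gene_ids = []
    gid = 0

    def add_gene(tss, vector, housekeeping=False):
        nonlocal gid
        name = f"G{gid:04d}"
        genes.append(
            {
                "gene_id": name,
                "chrom": "chr1",
                "tss": int(tss),
                "strand": "+",
                "housekeeping": int(housekeeping),
            }
        )
        expr[name] = vector
        gid += 1
        return name

    pos = 500_000
    truth_pairs = []
    for ci in range(n_clusters):
        base = rng.normal(0.0, 1.0, N_TISSUES)
        jitter = 0.1
        v1 = base + rng.normal(0.0, jitter, N_TISSUES)
        sign = -1.0 if ci % 2 else 1.0  # alternate similar/opposite patterns
        v2 = sign * base + rng.normal(0.0, jitter, N_TISSUES)
        g1 = add_gene(pos, v1)
        g2 = add_gene(pos + 100_000, v2)  # 100 kb apart: within the 400 kb rule
        cluster_gene_ids += [g1, g2]
        truth_pairs.append((g1, g2, sign))
        pos += spacing

    n_housekeeping = max(2, n_genes // 20)
    n_background = max(0, n_genes - 2 * n_clusters - n_housekeeping)
    for _ in range(n_background):
        add_gene(pos, rng.normal(0.0, 1.0, N_TISSUES))
        pos += spacing
    hk_base = rng.normal(0.0, 1.0, N_TISSUES)
    for j in range(n_housekeeping):
        # housekeeping genes co-express in a cluster but must be excluded
        add_gene(pos + j * 50_000, hk_base + rng.normal(0.0, 0.05, N_TISSUES),
                 housekeeping=True)
    pos += spacing

    genes_df = pd.DataFrame(genes)
    expression_df = pd.DataFrame(
        expr, index=[f"tissue_{t:02d}" for t in range(N_TISSUES)]
    ).T
    expression_df.index.name = "gene_id"

    tus = genes_df.assign(
        start=genes_df["tss"], end=genes_df["tss"] + gene_len
    )[["chrom", "start", "end", "gene_id"]]

    # conserved intergenic elements: biased placement around the primary gene
    # of each co-expressed pair, uniform placement around background genes (so
    # the randomization baseline sees a realistic unbiased landscape)
    boundaries_bp = np.asarray(scheme.boundaries) * 1000.0
    elements = []
    placed_domains = []
    elem_len = 200
    primary_genes = [pair[0] for pair in truth_pairs]
    uniform = np.full(len(scheme.labels), 1.0 / len(scheme.labels))

    def place_elements(gene, weights, record):
        for _ in range(elements_per_gene):
            dom = rng.choice(len(scheme.labels), p=weights)
            lo = max(boundaries_bp[dom], 3000 + elem_len)  # clear of the promoter rule
            hi = boundaries_bp[dom + 1]
            dist = rng.uniform(lo, hi)
            side = rng.choice([-1.0, 1.0])
            mid = gene["tss"] + side * dist
            start = int(mid - elem_len / 2)
            if start < 0:
                continue
            elements.append({"chrom": "chr1", "start": start, "end": start + elem_len})
            if record:
                placed_domains.append(scheme.labels[dom])

    primary_set = genes_df[genes_df["gene_id"].isin(primary_genes)]
    background_set = genes_df[
        ~genes_df["gene_id"].isin(cluster_gene_ids)
        & ~genes_df["housekeeping"].astype(bool)
    ]
    for _, gene in primary_set.iterrows():
        place_elements(gene, domain_bias, record=True)
    for _, gene in background_set.iterrows():
        place_elements(gene, uniform, record=False)
    # decoys: inside transcription units and promoters (must be filtered out)
    n_decoys = max(5, len(elements) // 20)
    for _, gene in primary_set.head(n_decoys).iterrows():
        elements.append(
            {"chrom": "chr1", "start": int(gene["tss"] + 2000),
             "end": int(gene["tss"] + 2000 + elem_len)}
        )
    elements_df = pd.DataFrame(elements).sort_values(["start"]).reset_index(drop=True)

    placed = pd.Series(placed_domains).value_counts(normalize=True)
    return GenomicFixture(
        genes=genes_df,
        expression=expression_df,
        conserved_elements=elements_df,
        transcription_units=tus,
        truth={
            "cluster_genes": cluster_gene_ids,
            "primary_genes": primary_genes,
            "pairs": truth_pairs,
            "domain_bias": {
                label: float(w) for label, w in zip(scheme.labels, domain_bias)
            },
            "placed_fraction": {k: float(v) for k, v in placed.items()},
            "n_decoys": n_decoys,
            "seed": seed,
        },
    )


def make_bands(
    chrom: str = "chr1",
    n_bands: int = 10,
    band_size: int = 5_000_000,
) -> pd.DataFrame:
    """Alternating Giemsa-negative / Giemsa-positive bands tiling a chromosome."""
    rows = []
    stains = ["gneg", "gpos75"]
    for i in range(n_bands):
        rows.append(
            {
                "chrom": chrom,
                "start": i * band_size,
                "end": (i + 1) * band_size,
                "name": f"q{i + 1}",
                "gieStain": stains[i % 2],
            }
        )
    return pd.DataFrame(rows)


def make_fragments(
    chrom: str = "chr1", length: int = 50_000_000, fragment_size: int = 4000
) -> pd.DataFrame:
    """Restriction fragments tiling [0, length) without gaps (HindIII-like)."""
    starts = np.arange(0, length, fragment_size)
    ends = np.minimum(starts + fragment_size, length)
    return pd.DataFrame(
        {
            "fragment_id": np.arange(len(starts)),
            "chrom": chrom,
            "start": starts,
            "end": ends,
        }
    )


def simulate_hic_tag_pairs(
    bands: pd.DataFrame,
    fragments: pd.DataFrame,
    class_domain_weights: Mapping[str, Sequence[float]],
    n_pairs: int = 2000,
    keep_fraction: float = 0.5,
    seed: int = 0,
    scheme: DomainScheme = DEFAULT_DOMAINS,
) -> pd.DataFrame:
    """Intra-band tag pairs with per-domain separation weights per band class.

    ``class_domain_weights`` maps band class ("gneg" / "gpos") to six domain
    weights.  Unique fragment pairs are emitted with multiplicity >= 4 for
    roughly ``keep_fraction`` of interactions (the rest get 1-3 copies), so
    the downstream multiplicity filter retains a controllable subset.  Pairs
    never span a band boundary.
    """
    rng = np.random.default_rng(seed)
    from .enrichment import classify_band  # shared Giemsa classification

    bands = bands.copy()
    bands["class"] = bands["gieStain"].map(classify_band)
    boundaries_bp = np.asarray(scheme.boundaries) * 1000.0

    frag_by_chrom = {c: g.sort_values("start") for c, g in fragments.groupby("chrom")}
    rows = []
    truth_rows = []
    classes = [c for c in ("gneg", "gpos") if c in set(bands["class"])]
    for _ in range(n_pairs):
        cls = classes[rng.integers(len(classes))]
        weights = np.asarray(class_domain_weights[cls], dtype=float)
        weights = weights / weights.sum()
        cands = bands[bands["class"] == cls]
        band = cands.iloc[rng.integers(len(cands))]
        frags = frag_by_chrom[band["chrom"]]
        in_band = frags[(frags["start"] >= band["start"]) & (frags["end"] <= band["end"])]
        if len(in_band) < 2:
            continue
        dom = rng.choice(len(weights), p=weights)
        sep = rng.uniform(boundaries_bp[dom], boundaries_bp[dom + 1])
        # anchor fragment with room for the separation inside the band
        max_start = band["end"] - sep - 1
        ok = in_band[in_band["start"] < max_start]
        if ok.empty:
            continue
        f1 = ok.iloc[rng.integers(len(ok))]
        # partner fragment whose 5' (direction 1) site sits ~sep downstream of
        # the 3' (direction 0) site of f1
        target = f1["end"] + sep
        starts = in_band["start"].to_numpy()
        idx = int(np.searchsorted(starts, target, side="right")) - 1
        if idx < 0 or idx >= len(in_band):
            continue
        f2 = in_band.iloc[idx]
        if f2["start"] <= f1["end"]:
            continue
        if f2["fragment_id"] == f1["fragment_id"]:
            continue
        multiplicity = (
            int(rng.integers(4, 7)) if rng.uniform() < keep_fraction else int(rng.integers(1, 4))
        )
        for _ in range(multiplicity):
            rows.append(
                {
                    "chrom": band["chrom"],
                    "fragment_1": int(f1["fragment_id"]),
                    "direction_1": 0,
                    "fragment_2": int(f2["fragment_id"]),
                    "direction_2": 1,
                }
            )
        truth_rows.append(
            {
                "chrom": band["chrom"],
                "fragment_1": int(f1["fragment_id"]),
                "fragment_2": int(f2["fragment_id"]),
                "band_class": cls,
                "separation_bp": float(f2["start"] - f1["end"]),
                "domain": scheme.labels[dom],
                "multiplicity": multiplicity,
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "fragment_1", "direction_1", "fragment_2", "direction_2"]
    )
    df.attrs["truth"] = {
        "interactions": pd.DataFrame(
            truth_rows,
            columns=[
                "chrom", "fragment_1", "fragment_2", "band_class",
                "separation_bp", "domain", "multiplicity",
            ],
        ),
        "class_domain_weights": {k: list(map(float, v)) for k, v in class_domain_weights.items()},
        "seed": seed,
    }
    return df
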