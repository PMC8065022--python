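"""Synthetic multi-study proteomics / transcriptomics data with known truth.

The generator emulates the statistical structure the integration pipeline
assumes: several studies measuring overlapping samples with study-specific
global intensity offsets (batch effects), lineage-structured true abundances
spanning several orders of magnitude, abundance-dependent (MNAR) plus random
(MCAR) missingness, paired mRNA matrices with configurable per-gene
mRNA–protein rank correlation, a small panel of anchor proteins with known
absolute abundance, and peptide-level detection fixtures with planted
tumour-specific classes.  Every stochastic choice is driven by a single seed
and the full ground truth is recorded for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    AnchorAbundances,
    AssayAnnotation,
    IntensityMatrix,
    PeptideEvidenceTable,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "PeptideFixtureTruth",
    "generate_multistudy",
    "generate_paired_rna",
    "generate_peptide_fixture",
]

_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic multi-study generator.

    Log-scale parameters are in log2 units.  ``dynamic_range_log2`` defaults
    to five orders of magnitude (≈16.6 log2 units), matching the span of
    absolute protein abundances (10^2–10^6 copies per cell) seen in anchor
    panels.  ``rna_correlation_distribution`` is the (location, spread) of
    the per-gene target Spearman distribution; ``rna_within_rs`` is the
    target within-sample (across genes) mRNA–protein Spearman.
    """

    n_proteins: int = 500
    n_studies: int = 3
    samples_per_lineage: Mapping[str, int] = field(
        default_factory=lambda: {"breast": 8, "colorectal": 8, "ovarian": 8}
    )
    sample_type: str | Sequence[str] = "mixed"
    batch_offset_sd: float = 1.0
    batch_protein_jitter_sd: float = 0.0
    noise_sd: float = 0.3
    lineage_sd: float = 0.5
    sample_sd: float = 0.5
    dynamic_range_log2: float = 5 * math.log2(10.0)
    base_log2_min: float = 10.0
    mnar_enabled: bool = True
    mnar_midpoint: float = 12.0
    mnar_slope: float = 1.0
    mcar_rate: float = 0.02
    anchor_count: int = 14
    anchor_rank_noise_sd: float = 0.0
    rna_correlation_distribution: tuple[float, float] = (0.31, 0.15)
    rna_within_rs: float = 0.58
    rna_base_log2_sd: float = 4.0
    rna_sample_sd: float = 0.5
    peptide_class_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "tumour_only_unique": 5,
            "tumour_only_ambiguous": 2,
            "tumour_unique_on_shared_protein": 2,
            "cell_line_only": 8,
            "shared": 12,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if not self.samples_per_lineage or any(
            c < 1 for c in self.samples_per_lineage.values()
        ):
            raise ValueError("each lineage needs at least one sample")
        total = sum(self.samples_per_lineage.values())
        if total < 2:
            raise ValueError("need at least two samples in total")
        if not 0.0 <= self.mcar_rate <= 1.0:
            raise ValueError("mcar_rate must lie in [0, 1]")
        if self.anchor_count > self.n_proteins:
            raise ValueError("anchor_count cannot exceed n_proteins")
        loc, spread = self.rna_correlation_distribution
        if not -1.0 <= loc <= 1.0 or spread < 0:
            raise ValueError("invalid rna_correlation_distribution")

    # ---- deterministic sample layout ------------------------------------

    def sample_layout(self) -> pd.DataFrame:
        """Assay table implied by the config (deterministic, no RNG).

        One assay per sample; samples cycle over studies so that every study
        spans several lineages (batch and lineage are not confounded).
        """
        rows = []
        idx = 0
        for lineage in sorted(self.samples_per_lineage):
            for i in range(self.samples_per_lineage[lineage]):
                if isinstance(self.sample_type, str):
                    if self.sample_type == "mixed":
                        stype = "cell_line" if i % 2 == 0 else "tumour"
                    else:
                        stype = self.sample_type
                else:
                    stype = self.sample_type[idx]
                sample_id = f"{lineage}_s{i}"
                rows.append(
                    {
                        "assay_id": f"assay_{sample_id}",
                        "study_id": f"study{idx % self.n_studies}",
                        "sample_id": sample_id,
                        "sample_type": stype,
                        "lineage": lineage,
                        "replicate_group": sample_id,
                        "enzyme": "trypsin",
                    }
                )
                idx += 1
        return pd.DataFrame(rows).set_index("assay_id")


@dataclass
class SyntheticTruth:
    """Realized ground truth behind one generated dataset."""

    true_log2_abundance: pd.DataFrame      # proteins × samples
    batch_offsets: pd.DataFrame            # proteins × studies, additive log2
    missing_mechanism: pd.DataFrame        # proteins × assays: "", "mnar", "mcar"
    gene_rs_targets: pd.Series             # per-gene target Spearman
    anchor_abundance: AnchorAbundances     # anchors × samples, copies per cell
    base_log2: pd.Series                   # per-protein grand log2 abundance
    annotation: AssayAnnotation
    config: GeneratorConfig

    def __post_init__(self) -> None:
        if set(self.anchor_abundance.protein_ids) - set(self.true_log2_abundance.index):
            raise ValueError("anchor proteins must be a subset of all proteins")


def generate_multistudy(
    config: GeneratorConfig,
) -> tuple[IntensityMatrix, AssayAnnotation, SyntheticTruth]:
    """Generate a raw-iBAQ multi-study intensity matrix with known truth.

    Observed intensity is ``2**(true_log2 + batch_offset + N(0, noise_sd))``;
    entries are then masked by a logistic MNAR curve on true log2 abundance
    and by uniform MCAR.  Samples of one lineage share a lineage mean profile
    plus an independent per-sample deviation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = config.sample_layout()
    annotation = AssayAnnotation(layout.copy())
    samples = layout["sample_id"].tolist()
    lineages = sorted(config.samples_per_lineage)
    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]
    n_p, n_s = config.n_proteins, len(samples)

    # True abundances: base (uniform over the dynamic range) + lineage
    # profile shared within a lineage + per-sample biological deviation.
    base = config.base_log2_min + config.dynamic_range_log2 * rng.random(n_p)
    lineage_fx = {
        lin: rng.normal(0.0, config.lineage_sd, size=n_p) for lin in lineages
    }
    sample_fx = rng.normal(0.0, config.sample_sd, size=(n_p, n_s))
    true_log2 = np.empty((n_p, n_s))
    for j, (assay, row) in enumerate(layout.iterrows()):
        true_log2[:, j] = base + lineage_fx[row["lineage"]] + sample_fx[:, j]

    # Study-wise additive log2 offsets (global, optional per-protein jitter).
    studies = sorted(layout["study_id"].unique())
    offsets = np.empty((n_p, len(studies)))
    for k, st in enumerate(studies):
        global_off = rng.normal(0.0, config.batch_offset_sd)
        jitter = (
            rng.normal(0.0, config.batch_protein_jitter_sd, size=n_p)
            if config.batch_protein_jitter_sd > 0
            else np.zeros(n_p)
        )
        offsets[:, k] = global_off + jitter
    study_idx = np.array([studies.index(s) for s in layout["study_id"]])

    noise = (
        rng.normal(0.0, config.noise_sd, size=(n_p, n_s))
        if config.noise_sd > 0
        else np.zeros((n_p, n_s))
    )
    observed_log2 = true_log2 + offsets[:, study_idx] + noise
    observed = np.exp2(observed_log2)

    # Missingness: MNAR first (logistic detection curve on true abundance),
    # then MCAR uniformly over the still-observed entries.
    mechanism = np.full((n_p, n_s), "", dtype=object)
    if config.mnar_enabled:
        p_detect = 1.0 / (
            1.0 + np.exp(-config.mnar_slope * (true_log2 - config.mnar_midpoint))
        )
        mnar_mask = rng.random((n_p, n_s)) > p_detect
        mechanism[mnar_mask] = "mnar"
    if config.mcar_rate > 0:
        mcar_mask = (rng.random((n_p, n_s)) < config.mcar_rate) & (mechanism == "")
        mechanism[mcar_mask] = "mcar"
    observed = np.where(mechanism == "", observed, np.nan)

    # Per-gene target Spearman for the paired mRNA layer (drawn here so the
    # full truth is fixed by one seed).
    loc, spread = config.rna_correlation_distribution
    rs_targets = np.clip(rng.normal(loc, spread, size=n_p), -0.9, 0.95)

    # Anchor proteins: copies per cell as a monotone map of true log2
    # abundance onto a 10^2–10^6 range, with optional rank noise.
    anchor_ids = sorted(rng.choice(proteins, size=config.anchor_count, replace=False))
    anchor_rows = [proteins.index(a) for a in anchor_ids]
    lo, hi = true_log2.min(), true_log2.max()
    anchor_log10 = 2.0 + 4.0 * (true_log2[anchor_rows, :] - lo) / max(hi - lo, 1e-12)
    if config.anchor_rank_noise_sd > 0:
        anchor_log10 = anchor_log10 + rng.normal(
            0.0, config.anchor_rank_noise_sd, size=anchor_log10.shape
        )
    anchors = AnchorAbundances(
        pd.DataFrame(10.0 ** anchor_log10, index=anchor_ids, columns=samples)
    )

    assay_ids = layout.index.tolist()
    matrix = IntensityMatrix(
        values=pd.DataFrame(observed, index=proteins, columns=assay_ids),
        stage="raw_ibaq",
    )
    truth = SyntheticTruth(
        true_log2_abundance=pd.DataFrame(true_log2, index=proteins, columns=samples),
        batch_offsets=pd.DataFrame(offsets, index=proteins, columns=studies),
        missing_mechanism=pd.DataFrame(mechanism, index=proteins, columns=assay_ids),
        gene_rs_targets=pd.Series(rs_targets, index=proteins),
        anchor_abundance=anchors,
        base_log2=pd.Series(base, index=proteins),
        annotation=annotation,
        config=config,
    )
    return matrix, annotation, truth


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (van der Waerden scores)."""
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.5) / len(x))


def _pearson_for_spearman(rs: float) -> float:
    """Gaussian-copula Pearson correlation realizing target Spearman ``rs``."""
    return 2.0 * math.sin(math.pi * rs / 6.0)


def generate_paired_rna(truth: SyntheticTruth, config: GeneratorConfig) -> pd.DataFrame:
    """Generate an FPKM-like mRNA matrix (genes × samples) paired to truth.

    Two couplings are built with Gaussian copulas: across genes, the
    gene-level mRNA baseline tracks protein baseline abundance at the
    within-sample target Spearman (``rna_within_rs``); across samples within
    each gene, the mRNA deviations track the protein's true deviations at
    that gene's target Spearman (``gene_rs_targets``).  Values are
    ``2**log2`` and therefore non-negative.
    """
    if truth is None:
        raise ValueError("truth must be generated first")
    rng = np.random.default_rng(config.seed + 1_000_003)
    true_log2 = truth.true_log2_abundance.to_numpy()
    genes = list(truth.true_log2_abundance.index)
    samples = list(truth.true_log2_abundance.columns)
    n_g, n_s = true_log2.shape

    # Gene-level baseline coupled to protein baseline across genes.  The
    # copula correlation is (i) inflated analytically to undo the attenuation
    # caused by the lineage/sample noise on the protein side and the
    # per-sample mRNA deviations on the mRNA side, and (ii) realized exactly
    # in-sample by orthogonalizing the innovation against the baseline
    # scores, so the configured within-sample Spearman target is met without
    # generation-level sampling drift.
    rho_w = _pearson_for_spearman(config.rna_within_rs)
    sigma_b = config.dynamic_range_log2 / math.sqrt(12.0)
    lam_protein = sigma_b / math.sqrt(
        sigma_b**2 + config.lineage_sd**2 + config.sample_sd**2
    )
    lam_rna = config.rna_base_log2_sd / math.sqrt(
        config.rna_base_log2_sd**2 + config.rna_sample_sd**2
    )
    rho_use = min(rho_w / (lam_protein * lam_rna), 0.999)
    zb = _normal_scores(truth.base_log2.to_numpy())
    zb = (zb - zb.mean()) / zb.std()
    eps_g = rng.normal(0.0, 1.0, size=n_g)
    eps_g = eps_g - zb * (eps_g @ zb) / (zb @ zb)   # exact in-sample orthogonality
    eps_g = (eps_g - eps_g.mean()) / eps_g.std()
    gene_base = config.rna_base_log2_sd * (
        rho_use * zb + math.sqrt(max(0.0, 1.0 - rho_use**2)) * eps_g
    ) + 5.0

    # Per-gene sample deviations coupled to the protein's true deviations.
    rs_targets = truth.gene_rs_targets.to_numpy()
    eps_s = rng.normal(0.0, 1.0, size=(n_g, n_s))
    dev = np.empty((n_g, n_s))
    for g in range(n_g):
        rho_g = _pearson_for_spearman(float(rs_targets[g]))
        u = _normal_scores(true_log2[g, :])
        dev[g, :] = rho_g * u + math.sqrt(max(0.0, 1.0 - rho_g**2)) * eps_s[g, :]

    rna_log2 = gene_base[:, None] + config.rna_sample_sd * dev
    return pd.DataFrame(np.exp2(rna_log2), index=genes, columns=samples)


@dataclass
class PeptideFixtureTruth:
    """Planted peptide classes and the implied tumour-specific protein set."""

    class_of_peptide: dict[str, str]
    tumour_only_peptides: frozenset[str]
    tumour_only_unique_peptides: frozenset[str]
    tumour_specific_proteins: frozenset[str]
    class_counts: dict[str, int]


def generate_peptide_fixture(
    config: GeneratorConfig,
) -> tuple[PeptideEvidenceTable, PeptideFixtureTruth]:
    """Build a peptide evidence table with planted detection classes.

    Classes: ``tumour_only_unique`` peptides each mark one planted
    tumour-specific protein; ``tumour_only_ambiguous`` peptides map to two
    proteins and must be dropped by the unique-mapping rule;
    ``tumour_unique_on_shared_protein`` peptides are unique and tumour-only
    but their protein also carries shared evidence, so the protein must not
    be called tumour-specific; ``cell_line_only`` and ``shared`` fill the
    background.
    """
    config.validate()
    layout = config.sample_layout()
    tumour_assays = layout.index[layout["sample_type"] == "tumour"].tolist()
    cell_assays = layout.index[layout["sample_type"] == "cell_line"].tolist()
    if not tumour_assays:
        raise ValueError("peptide fixture requires at least one tumour assay")
    if not cell_assays:
        raise ValueError("peptide fixture requires at least one cell-line assay")

    rng = np.random.default_rng(config.seed + 7)
    counts = dict(config.peptide_class_counts)
    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]
    needed = (
        counts.get("tumour_only_unique", 0)
        + 2 * counts.get("tumour_only_ambiguous", 0)
        + counts.get("tumour_unique_on_shared_protein", 0)
        + counts.get("cell_line_only", 0)
        + counts.get("shared", 0)
    )
    if needed > len(proteins):
        raise ValueError("n_proteins too small for the requested peptide classes")
    pool = list(rng.permutation(proteins))

    def new_peptide() -> str:
        length = int(rng.integers(8, 16))
        return "".join(rng.choice(_AMINO, size=length))

    def detect_in(assays: list[str]) -> list[str]:
        k = int(rng.integers(1, len(assays) + 1))
        return list(rng.choice(assays, size=k, replace=False))

    mapping: dict[str, frozenset[str]] = {}
    det_rows: list[tuple[str, str, bool]] = []
    class_of: dict[str, str] = {}
    tumour_specific: set[str] = set()

    def add(pep: str, prots: frozenset[str], assays: list[str], cls: str) -> None:
        mapping[pep] = prots
        class_of[pep] = cls
        for a in assays:
            det_rows.append((pep, a, True))

    for _ in range(counts.get("tumour_only_unique", 0)):
        prot = pool.pop()
        tumour_specific.add(prot)
        add(new_peptide(), frozenset({prot}), detect_in(tumour_assays), "tumour_only_unique")
    for _ in range(counts.get("tumour_only_ambiguous", 0)):
        prots = frozenset({pool.pop(), pool.pop()})
        add(new_peptide(), prots, detect_in(tumour_assays), "tumour_only_ambiguous")
    for _ in range(counts.get("tumour_unique_on_shared_protein", 0)):
        prot = pool.pop()
        add(new_peptide(), frozenset({prot}), detect_in(tumour_assays),
            "tumour_unique_on_shared_protein")
        # the same protein also carries evidence in a cell line
        add(new_peptide(), frozenset({prot}),
            detect_in(cell_assays), "shared_support")
    for _ in range(counts.get("cell_line_only", 0)):
        add(new_peptide(), frozenset({pool.pop()}), detect_in(cell_assays), "cell_line_only")
    for _ in range(counts.get("shared", 0)):
        assays = detect_in(tumour_assays) + detect_in(cell_assays)
        add(new_peptide(), frozenset({pool.pop()}), assays, "shared")

    detections = pd.DataFrame(
        det_rows, columns=["peptide_sequence", "assay_id", "detected"]
    )
    table = PeptideEvidenceTable(mapping=mapping, detections=detections)
    tumour_only = frozenset(
        p for p, c in class_of.items()
        if c in ("tumour_only_unique", "tumour_only_ambiguous",
                 "tumour_unique_on_shared_protein")
    )
    unique = frozenset(p for p in tumour_only if len(mapping[p]) == 1)
    truth = PeptideFixtureTruth(
        class_of_peptide=class_of,
        tumour_only_peptides=tumour_only,
        tumour_only_unique_peptides=unique,
        tumour_specific_proteins=frozenset(tumour_specific),
        class_counts={c: sum(1 for v in class_of.values() if v == c) for c in set(class_of.values())},
    )
    return table, truth
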