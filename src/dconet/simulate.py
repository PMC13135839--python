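"""Synthetic two-group transcriptome + proteome studies.

The generator emulates a small two-group (fertile vs. subfertile)
blood multi-omics design: negative-binomial RNA-seq counts with a
planted fraction of differentially expressed genes, log-normal protein
abundances with planted differentially abundant proteins and
missing-at-random cells, a planted transcription factor whose coupling
to its differentially expressed targets exists in only one group, and
a planted hub gene whose network connectivity differs between groups.
Every planted effect is recorded in a ground-truth object so each
downstream stage can be validated against what was actually simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    PROTEIN,
    TRANSCRIPT,
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic two-group study.

    Defaults mirror the emulated design: 6 samples per group, an 8%
    planted DEG/DAP fraction with |log2FC| = 2, NB dispersion 0.1,
    log2-scale protein noise SD 0.5, 5% protein missingness, and a
    third of proteins mapped to a gene.
    """

    n_genes: int = 600
    n_proteins: int = 300
    n_per_group: int = 6
    frac_de: float = 0.08
    lfc_de: float = 2.0
    nb_dispersion: float = 0.1
    protein_sd: float = 0.5
    frac_missing: float = 0.05
    n_tf: int = 50
    n_targets: int = 20
    hub_degree: int = 25
    overlap_frac: float = 0.33
    cross_coupling: float = 0.2
    frac_low_expressed: float = 0.2
    coupled_group: str = "fertile"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_missing", "overlap_frac",
                     "frac_low_expressed"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_proteins", "n_per_group"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_per_group < 3:
            raise ValidationError("n_per_group must be >= 3")
        if self.nb_dispersion < 0 or self.protein_sd < 0:
            raise ValidationError("noise parameters must be non-negative")


@dataclass
class GroundTruth:
    """What was planted: signed log2 fold changes of the DE features,
    the rewired regulator with its targets and coupled group, and the
    differential-connectivity hub with its partners."""

    de_lfc: dict[str, float] = field(default_factory=dict)
    dap_lfc: dict[str, float] = field(default_factory=dict)
    regulator_id: str | None = None
    regulator_targets: list[str] = field(default_factory=list)
    coupled_group: str = "fertile"
    hub_id: str | None = None
    hub_partners: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"feature_id": g, "role": "de_gene", "lfc": lfc, "detail": ""}
            for g, lfc in sorted(self.de_lfc.items())
        ] + [
            {"feature_id": p, "role": "dap_protein", "lfc": lfc, "detail": ""}
            for p, lfc in sorted(self.dap_lfc.items())
        ]
        if self.regulator_id:
            rows.append({"feature_id": self.regulator_id, "role": "regulator",
                         "lfc": 0.0, "detail": self.coupled_group})
            rows += [{"feature_id": t, "role": "regulator_target", "lfc": 0.0,
                      "detail": self.regulator_id} for t in self.regulator_targets]
        if self.hub_id:
            rows.append({"feature_id": self.hub_id, "role": "hub", "lfc": 0.0,
                         "detail": self.coupled_group})
            rows += [{"feature_id": h, "role": "hub_partner", "lfc": 0.0,
                      "detail": self.hub_id} for h in self.hub_partners]
        return pd.DataFrame(rows, columns=["feature_id", "role", "lfc", "detail"])


@dataclass
class SimStudy:
    """A complete synthetic study: both matrices, the design, the TF
    list, the protein-to-gene mapping, and the ground truth."""

    counts: ExpressionMatrix
    abundance: ExpressionMatrix
    design: SampleDesign
    tf_ids: list[str]
    mapping: pd.Series  # protein_id -> gene_id
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, str]:
        from . import io as dio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "abundance": outdir / "abundance.tsv",
            "design": outdir / "design.tsv",
            "tf_list": outdir / "tf_list.tsv",
            "mapping": outdir / "mapping.tsv",
            "truth": outdir / "truth.tsv",
        }
        dio.write_matrix(self.counts, paths["counts"])
        dio.write_matrix(self.abundance, paths["abundance"])
        dio.write_design(self.design, paths["design"])
        pd.DataFrame({"tf_id": self.tf_ids}).to_csv(
            paths["tf_list"], sep="\t", index=False)
        pd.DataFrame({"protein_id": self.mapping.index,
                      "gene_id": self.mapping.values}).to_csv(
            paths["mapping"], sep="\t", index=False)
        self.truth.as_frame().to_csv(paths["truth"], sep="\t", index=False,
                                     float_format="%.4f")
        return {k: str(v) for k, v in paths.items()}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture (Poisson when the
    dispersion is zero)."""
    mean = np.clip(mean, 1e-8, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleDesign, GroundTruth, np.ndarray]:
    """Simulate the count matrix with planted DEGs.

    Baseline log2 means are normal(5, 2) for expressed genes and
    normal(-3, 1) for a low-expressed fraction (so the CPM filter has
    work to do); per-sample size factors are log-uniform in
    [0.7, 1.4]; counts are NB with a single global dispersion; planted
    DEGs have their subfertile-group mean scaled by 2^(+/-lfc_de).
    Returns the matrix, design, ground truth and the size factors used
    (the regulator/hub planting steps reuse them).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    samples = [f"F{i+1}" for i in range(cfg.n_per_group)] + [
        f"S{i+1}" for i in range(cfg.n_per_group)]
    groups = pd.Series(
        ["fertile"] * cfg.n_per_group + ["subfertile"] * cfg.n_per_group,
        index=samples,
    )
    design = SampleDesign(groups)

    n_low = int(round(cfg.frac_low_expressed * cfg.n_genes))
    log2_mu = rng.normal(5.0, 2.0, size=cfg.n_genes)
    low_idx = rng.choice(cfg.n_genes, size=n_low, replace=False)
    log2_mu[low_idx] = rng.normal(-3.0, 1.0, size=n_low)

    # planted structure lives among reliably expressed genes
    expressed_idx = np.setdiff1d(np.arange(cfg.n_genes), low_idx)
    special_pool = expressed_idx[log2_mu[expressed_idx] >= 3.0]
    n_de = int(round(cfg.frac_de * cfg.n_genes))
    n_special = n_de + cfg.n_tf + 1 + cfg.hub_degree
    if len(special_pool) < n_special:
        raise ValidationError(
            "not enough well-expressed genes for the requested planted "
            f"structure ({len(special_pool)} < {n_special})"
        )
    picked = rng.choice(special_pool, size=n_special, replace=False)
    de_idx = picked[:n_de]
    tf_idx = picked[n_de:n_de + cfg.n_tf]
    hub_idx = int(picked[n_de + cfg.n_tf]) if cfg.hub_degree > 0 else None
    partner_idx = picked[n_de + cfg.n_tf + 1:]

    truth = GroundTruth(coupled_group=cfg.coupled_group)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    for i, s in zip(de_idx, signs):
        truth.de_lfc[genes[i]] = float(s * cfg.lfc_de)
    if cfg.n_targets > 0:
        if cfg.n_tf < 1:
            raise ValidationError("planting a regulator requires n_tf >= 1")
        # targets are same-direction (up) DEGs: a coherent regulon, and
        # the PIF weights do not cancel across targets
        up_idx = [int(i) for i, s in zip(de_idx, signs) if s > 0]
        if cfg.n_targets > len(up_idx):
            raise ValidationError(
                f"n_targets={cfg.n_targets} exceeds the "
                f"{len(up_idx)} up-regulated planted DEGs"
            )
        truth.regulator_id = genes[int(tf_idx[0])]
        truth.regulator_targets = [genes[i] for i in up_idx[:cfg.n_targets]]
    if cfg.hub_degree > 0:
        # the hub itself is a planted DEG (outside the regulon) so its
        # edges pass the anchor rule
        target_set = set(truth.regulator_targets)
        candidates = [int(i) for i in de_idx if genes[int(i)] not in target_set]
        if not candidates:
            raise ValidationError("no DEG left to serve as the hub")
        truth.hub_id = genes[candidates[-1]]
        truth.hub_partners = [genes[int(i)] for i in partner_idx]

    sf = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=len(samples)))
    is_sub = (groups == "subfertile").to_numpy()

    mu = np.outer(2.0 ** log2_mu, sf)
    lfc_vec = np.array([truth.de_lfc.get(g, 0.0) for g in genes])
    mu[:, is_sub] *= (2.0 ** lfc_vec)[:, None]
    counts = _nb_draw(rng, mu, cfg.nb_dispersion).astype(int)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), TRANSCRIPT)
    return matrix, design, truth, sf


def _couple_to_driver(
    rng: np.random.Generator,
    counts: np.ndarray,
    gene_pos: dict[str, int],
    driver: str,
    followers: list[str],
    sample_mask: np.ndarray,
    sf: np.ndarray,
    log2_base: dict[str, float],
    slope: float,
) -> None:
    """Overwrite follower counts in the masked samples so that their
    log expression tracks the driver's (Poisson noise only).

    The driver signal is taken on the size-factor-corrected scale so
    the coupling survives library-size normalization downstream.
    """
    drv = counts[gene_pos[driver]][sample_mask].astype(float) / sf[sample_mask]
    z = np.log2(drv + 1.0)
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    for f in followers:
        mean = 2.0 ** (log2_base[f] + slope * z) * sf[sample_mask]
        counts[gene_pos[f], sample_mask] = rng.poisson(np.clip(mean, 1e-8, None))


def plant_regulator_and_hub(
    counts: ExpressionMatrix,
    design: SampleDesign,
    truth: GroundTruth,
    cfg: SimulationConfig,
    sf: np.ndarray,
) -> ExpressionMatrix:
    """Plant the rewired regulator and the differential-connectivity hub.

    In the coupled group only, regulator targets (and hub partners)
    are regenerated to track the regulator's (hub's) log expression
    with Poisson noise, giving pairwise correlations above 0.9 in
    expectation; in the other group they keep their independent draws.
    """
    if not truth.regulator_targets and not truth.hub_partners:
        return counts
    rng = np.random.default_rng(cfg.seed + 1)
    values = counts.values().astype(float)
    gene_pos = {g: i for i, g in enumerate(counts.feature_ids)}
    coupled_mask = np.asarray(
        [g == truth.coupled_group for g in design.groups.loc[counts.sample_ids]]
    )
    is_sub = np.asarray(
        [g == "subfertile" for g in design.groups.loc[counts.sample_ids]]
    )

    def base_of(g: str) -> float:
        obs = values[gene_pos[g]][~coupled_mask]
        base = float(np.log2(np.mean(obs / sf[~coupled_mask]) + 0.5))
        # remove the planted DE shift if the uncoupled samples carry it
        if is_sub[~coupled_mask].all():
            base -= truth.de_lfc.get(g, 0.0)
        return base

    sub_in_coupled = is_sub[coupled_mask].all()
    if truth.regulator_targets:
        bases = {
            t: base_of(t) + (truth.de_lfc.get(t, 0.0) if sub_in_coupled else 0.0)
            for t in truth.regulator_targets
        }
        _couple_to_driver(rng, values, gene_pos, truth.regulator_id,
                          truth.regulator_targets, coupled_mask, sf, bases,
                          slope=1.0)
    if truth.hub_partners:
        bases = {h: base_of(h) for h in truth.hub_partners}
        _couple_to_driver(rng, values, gene_pos, truth.hub_id,
                          truth.hub_partners, coupled_mask, sf, bases,
                          slope=1.2)
    return ExpressionMatrix(
        pd.DataFrame(values.astype(int), index=counts.feature_ids,
                     columns=counts.sample_ids),
        TRANSCRIPT,
    )


def simulate_proteins(
    cfg: SimulationConfig,
    truth: GroundTruth,
    counts: ExpressionMatrix,
    design: SampleDesign,
    sf: np.ndarray,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Simulate protein abundances and the protein-to-gene mapping.

    Mapped proteins track their gene's log2 normalized signal with a
    weak coupling (default 0.2, reproducing the near-zero cross-layer
    fold-change correlation typical of these designs) plus independent
    log-normal noise; planted DAPs are shifted by +/-lfc_de in the
    subfertile group; a fraction of cells is missing completely at
    random.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    proteins = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    samples = counts.sample_ids
    is_sub = np.asarray([g == "subfertile"
                         for g in design.groups.loc[samples]])

    n_mapped = int(round(cfg.overlap_frac * cfg.n_proteins))
    gene_ids = np.asarray(counts.feature_ids)
    gene_vals = counts.values() / sf  # normalized counts
    expressed = gene_vals.mean(axis=1) >= 4.0
    pool = np.flatnonzero(expressed)
    n_mapped = min(n_mapped, len(pool))
    mapped_gene_idx = rng.choice(pool, size=n_mapped, replace=False)
    mapping = pd.Series(
        gene_ids[mapped_gene_idx], index=proteins[:n_mapped], dtype=object)

    n_dap = int(round(cfg.frac_de * cfg.n_proteins))
    dap_pos = rng.choice(cfg.n_proteins, size=n_dap, replace=False)
    dap_signs = np.where(np.arange(n_dap) % 2 == 0, 1.0, -1.0)
    dap_shift = np.zeros(cfg.n_proteins)
    for pos, s in zip(dap_pos, dap_signs):
        dap_shift[pos] = s * cfg.lfc_de
        truth.dap_lfc[proteins[pos]] = float(s * cfg.lfc_de)

    base = rng.normal(20.0, 2.0, size=cfg.n_proteins)
    log2_abund = np.empty((cfg.n_proteins, len(samples)))
    gene_signal = np.log2(gene_vals + 0.5)
    # center within each group: the coupling transmits sample-level
    # covariation but not the planted fold changes, keeping the
    # cross-layer fold-change correlation weak as in real designs
    for mask in (is_sub, ~is_sub):
        gene_signal[:, mask] -= gene_signal[:, mask].mean(
            axis=1, keepdims=True)
    for i in range(cfg.n_proteins):
        noise = rng.normal(0.0, cfg.protein_sd, size=len(samples))
        signal = np.zeros(len(samples))
        if i < n_mapped:
            signal = cfg.cross_coupling * gene_signal[mapped_gene_idx[i]]
        log2_abund[i] = base[i] + signal + noise + dap_shift[i] * is_sub

    abund = 2.0 ** log2_abund
    if cfg.frac_missing > 0:
        miss = rng.random(abund.shape) < cfg.frac_missing
        abund[miss] = np.nan
    matrix = ExpressionMatrix(
        pd.DataFrame(abund, index=proteins, columns=samples), PROTEIN)
    return matrix, mapping


def simulate_study(cfg: SimulationConfig) -> SimStudy:
    """Generate a full synthetic study (counts, proteins, design,
    TF list, mapping, ground truth) reproducibly from cfg.seed."""
    counts, design, truth, sf = simulate_counts(cfg)
    counts = plant_regulator_and_hub(counts, design, truth, cfg, sf)
    abundance, mapping = simulate_proteins(cfg, truth, counts, design, sf)
    genes = counts.feature_ids
    # TF list: the regulator (if any) plus the other TF-labelled genes
    rng = np.random.default_rng(cfg.seed + 3)
    de_set = set(truth.de_lfc)
    non_special = [g for g in genes if g not in de_set]
    tf_ids = sorted(
        {truth.regulator_id} - {None}
        | set(rng.choice(non_special, size=max(cfg.n_tf - 1, 0), replace=False))
    )
    return SimStudy(counts=counts, abundance=abundance, design=design,
                    tf_ids=tf_ids, mapping=mapping, truth=truth, config=cfg)


def make_gene_sets(
    study: SimStudy,
    n_random_sets: int = 20,
    set_size: int = 15,
    seed: int | None = None,
) -> GeneSetCollection:
    """Gene-set collection for enrichment tests: one set of planted
    up-regulated genes, one of down-regulated genes, and random sets
    drawn from the gene universe."""
    rng = np.random.default_rng(
        study.config.seed + 4 if seed is None else seed)
    genes = study.counts.feature_ids
    sets: dict[str, list[str]] = {}
    up = sorted(g for g, l in study.truth.de_lfc.items() if l > 0)
    down = sorted(g for g, l in study.truth.de_lfc.items() if l < 0)
    if len(up) >= MIN_PLANTED_SET:
        sets["planted_up"] = up
    if len(down) >= MIN_PLANTED_SET:
        sets["planted_down"] = down
    for i in range(n_random_sets):
        members = sorted(rng.choice(genes, size=set_size, replace=False))
        sets[f"random_{i:02d}"] = list(members)
    descriptions = {name: "synthetic gene set" for name in sets}
    return GeneSetCollection(sets, descriptions)


MIN_PLANTED_SET = 5
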