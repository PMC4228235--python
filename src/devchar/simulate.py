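"""Synthetic expression data with the structure the pipeline assumes.

Two generators mirror the two study designs the pipeline analyses:

* a duplicated developmental time series in which a planted minority of genes
  follow smooth temporal programs (monotone logistic ramps, stage-switch
  steps, transient pulses) on top of gene-specific baselines, so the leading
  principal components of the sample cloud are driven by the planted genes;
* a paired two-condition cohort with a pair-shared random baseline
  (pairing-induced correlation) and a planted fraction of differentially
  expressed genes shifted in condition A on the log2 scale.

Noise is Gaussian on the log2 scale, the conventional log-normal-intensity
assumption for microarray data.  Every generator is a pure function of its
config: identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (DataError, ExpressionMatrix, ProbeGeneMap, SampleMetadata)
from .diffexpr import PairedDesign

# Default age grid (days on one monotone axis): a murine whole-lung series,
# embryonic days as days post conception and postnatal days offset by a
# 19.5-day gestation, covering pseudoglandular through alveolar stages.
MOUSE_GESTATION_DAYS = 19.5
DEFAULT_TIMEPOINTS = tuple(
    [9.5, 12.5, 14.5, 16.5, 18.5]
    + [MOUSE_GESTATION_DAYS + p for p in (0, 2, 4, 7, 11, 13, 18, 24, 30, 56)]
)

PROGRAM_TYPES = ("monotone", "switch", "transient")


@dataclass
class DevSeriesConfig:
    """Duplicated developmental time-series generator settings.

    ``effect_amp`` is the peak-to-trough amplitude of a planted temporal
    program and ``noise_sd`` the per-measurement Gaussian noise, both in log2
    units; the defaults (1.5 and 0.5) give the 3:1 signal-to-noise regime of
    a strong developmental program against typical array noise.
    """

    seed: int
    n_genes: int = 2000
    timepoints: tuple = DEFAULT_TIMEPOINTS
    n_replicates: int = 2
    n_characteristic: int | None = None   # default: 5% of n_genes
    program_types: tuple = PROGRAM_TYPES
    effect_amp: float = 1.5
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    increasing_fraction: float = 0.75   # share of monotone/switch programs going up

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, float)
        if tp.size < 4 or np.any(np.diff(tp) <= 0):
            raise DataError("timepoints must be strictly increasing, length >= 4")
        if self.n_characteristic is None:
            self.n_characteristic = max(1, int(round(0.05 * self.n_genes)))
        if not (0 <= self.n_characteristic < self.n_genes):
            raise DataError("n_characteristic must be < n_genes")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if self.n_replicates != 2:
            raise DataError("generator emulates biological duplicates (n_replicates = 2)")
        bad = set(self.program_types) - set(PROGRAM_TYPES)
        if bad or not self.program_types:
            raise DataError(f"unknown program types: {sorted(bad)}")


def _temporal_program(kind: str, u: np.ndarray, rng: np.random.Generator,
                      direction: float) -> np.ndarray:
    """Unit peak-to-trough program over normalized time u in [0, 1], mean 0.

    Each program family is anchored at a canonical developmental epoch with
    modest gene-to-gene jitter: stage transitions coordinate large gene
    cohorts, which is what makes the planted minority drive the dominant
    sample-variation axes.
    """
    if kind == "monotone":
        center = rng.uniform(0.4, 0.6)
        steep = rng.uniform(8.0, 12.0)
        prog = 1.0 / (1.0 + np.exp(-steep * (u - center)))
    elif kind == "switch":
        cut = rng.uniform(0.45, 0.55)
        prog = (u >= cut).astype(float)
    else:  # transient pulse around the mid-gestational epoch
        center = rng.uniform(0.45, 0.55)
        width = rng.uniform(0.15, 0.25)
        prog = np.exp(-0.5 * ((u - center) / width) ** 2)
    span = prog.max() - prog.min()
    if span > 0:
        prog = prog / span
    return direction * (prog - prog.mean())


def simulate_dev_timeseries(cfg: DevSeriesConfig):
    """Generate (ExpressionMatrix, SampleMetadata, truth) for a duplicate series.

    ``truth`` is a DataFrame with one row per gene (``gene_id``,
    ``is_characteristic``, ``program_type``, ``direction``).  A planted gene
    shares its program across both replicates; noise is independent.
    """
    rng = np.random.default_rng(cfg.seed)
    tp = np.asarray(cfg.timepoints, float)
    n_t = tp.size
    u = (tp - tp.min()) / (tp.max() - tp.min())
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    planted = rng.choice(cfg.n_genes, size=cfg.n_characteristic, replace=False)
    planted_mask = np.zeros(cfg.n_genes, bool)
    planted_mask[planted] = True

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    signal = np.zeros((cfg.n_genes, n_t))
    ptype = np.array([""] * cfg.n_genes, dtype=object)
    direction = np.zeros(cfg.n_genes)
    for gi in planted:
        kind = cfg.program_types[rng.integers(len(cfg.program_types))]
        sign = 1.0 if rng.random() < cfg.increasing_fraction else -1.0
        signal[gi] = cfg.effect_amp * _temporal_program(kind, u, rng, sign)
        ptype[gi] = kind
        direction[gi] = sign

    sample_ids, cols, meta_rows = [], [], []
    for rep in (1, 2):
        noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_t))
        block = baseline[:, None] + signal + noise
        for j, age in enumerate(tp):
            sid = f"s{rep}_{j:02d}"
            sample_ids.append(sid)
            cols.append(block[:, j])
            meta_rows.append((sid, age, f"r{rep}", "", ""))
    data = pd.DataFrame(np.column_stack(cols), index=pd.Index(genes, name="feature_id"),
                        columns=sample_ids)
    meta = SampleMetadata(pd.DataFrame(
        meta_rows, columns=["sample_id", "age_days", "replicate_id", "group", "pair_id"]))
    truth = pd.DataFrame({
        "gene_id": genes,
        "is_characteristic": planted_mask,
        "program_type": ptype,
        "direction": direction,
    })
    return ExpressionMatrix(data, feature_level="gene"), meta, truth


@dataclass
class PairedCohortConfig:
    """Paired two-condition cohort generator settings.

    Defaults emulate a sibling-pair LCL cohort: 95 pairs, 5% of genes
    differentially expressed with a one-log2-unit shift against 0.4 log2
    units of measurement noise and a 0.5 log2-unit pair-shared baseline.
    """

    seed: int
    n_genes: int = 2000
    n_pairs: int = 95
    de_fraction: float = 0.05
    effect_log2: float = 1.0
    noise_sd: float = 0.4
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    pair_sd: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.de_fraction < 1):
            raise DataError("de_fraction must lie in [0, 1)")
        if self.de_fraction > 0 and self.de_fraction * self.n_genes < 1:
            raise DataError("de_fraction * n_genes must be >= 1 when nonzero")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if self.n_pairs < 2:
            raise DataError("need at least 2 pairs")


def simulate_paired_cohort(cfg: PairedCohortConfig):
    """Generate (ExpressionMatrix, SampleMetadata, PairedDesign, truth genes).

    Within each pair the two samples share a gene-specific random baseline,
    inducing the within-pair correlation a paired test exploits; planted DE
    genes are shifted by ``effect_log2`` in condition A.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    planted = rng.choice(cfg.n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    planted_mask = np.zeros(cfg.n_genes, bool)
    planted_mask[planted] = True

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    pair_fx = rng.normal(0.0, cfg.pair_sd, size=(cfg.n_genes, cfg.n_pairs))
    base = mu[:, None] + pair_fx
    a_vals = base + cfg.effect_log2 * planted_mask[:, None] \
        + rng.normal(0.0, cfg.noise_sd, size=base.shape)
    b_vals = base + rng.normal(0.0, cfg.noise_sd, size=base.shape)

    sample_ids, cols, meta_rows, pairs = [], [], [], []
    for p in range(cfg.n_pairs):
        sa, sb = f"p{p:03d}_A", f"p{p:03d}_B"
        sample_ids += [sa, sb]
        cols += [a_vals[:, p], b_vals[:, p]]
        meta_rows.append((sa, 0.0, "", "A", f"p{p:03d}"))
        meta_rows.append((sb, 0.0, "", "B", f"p{p:03d}"))
        pairs.append((sa, sb))
    data = pd.DataFrame(np.column_stack(cols), index=pd.Index(genes, name="feature_id"),
                        columns=sample_ids)
    meta = SampleMetadata(pd.DataFrame(
        meta_rows, columns=["sample_id", "age_days", "replicate_id", "group", "pair_id"]))
    design = PairedDesign(pairs, "A", "B")
    truth = {genes[i] for i in planted}
    return ExpressionMatrix(data, feature_level="gene"), meta, design, truth


@dataclass
class ProbeSimulation:
    """Probe-to-gene map plus the rule expanding a gene matrix to probe level."""

    probe_map: ProbeGeneMap
    good_probes: dict              # gene_id -> probe_id with low measurement noise
    probe_noise_sd: float
    good_noise_sd: float
    seed: int

    def expand(self, mat: ExpressionMatrix) -> ExpressionMatrix:
        """Probe rows = gene row + independent Gaussian noise.

        The designated good probe of each gene gets ``good_noise_sd`` noise,
        the rest ``probe_noise_sd``, so replicate-correlation collapse has a
        well-defined argmax.  Deterministic given the simulation seed.
        """
        rng = np.random.default_rng(self.seed + 1)
        tab = self.probe_map.table
        missing = set(tab["gene_id"]) - set(mat.feature_ids)
        if missing:
            raise DataError(f"genes in probe map absent from matrix: {sorted(missing)[:5]}")
        rows, ids = [], []
        for probe, gene in zip(tab["probe_id"], tab["gene_id"]):
            sd = self.good_noise_sd if self.good_probes[gene] == probe else self.probe_noise_sd
            rows.append(mat.data.loc[gene].to_numpy()
                        + rng.normal(0.0, sd, size=mat.shape[1]))
            ids.append(probe)
        data = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="feature_id"),
                            columns=mat.data.columns)
        return ExpressionMatrix(data, feature_level="probe")


def simulate_probe_map(gene_ids, max_probes_per_gene: int, seed: int,
                       probe_noise_sd: float = 0.3,
                       good_noise_sd: float = 0.05) -> ProbeSimulation:
    """Assign each gene 1..max probes; one designated low-noise representative."""
    if max_probes_per_gene < 1:
        raise DataError("max_probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    rows, good = [], {}
    for gene in gene_ids:
        k = int(rng.integers(1, max_probes_per_gene + 1))
        probes = [f"{gene}_p{j}" for j in range(1, k + 1)]
        good[gene] = probes[int(rng.integers(k))]
        rows += [(p, gene) for p in probes]
    pmap = ProbeGeneMap(pd.DataFrame(rows, columns=["probe_id", "gene_id"]))
    return ProbeSimulation(pmap, good, probe_noise_sd, good_noise_sd, seed)
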