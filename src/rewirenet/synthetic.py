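"""Two-condition count simulator with planted DE and TF-target rewiring.

The generator emulates a 6-vs-6 bulk RNA-seq contrast: ~thousands of
negative-binomial genes, a subset of which are transcription factors (TFs)
that each drive a module of target genes through a shared per-sample latent
factor. The strength of the TF-target coupling is condition-specific, so a
module whose coupling differs between conditions is "rewired" and its TF is a
ground-truth positive for regulator-prioritization methods.

Generative model, per condition ``c`` and sample ``s``::

    log mu[g, s] = base[g] + lfc[g]*ln2*[c == treatment]
                   + latent_sd * x[g, s] - latent_sd^2 / 2      (module genes)
    x[TF, s]     = f[m, s]
    x[tgt, s]    = coupling * f[m, s] + sqrt(1 - coupling^2) * eps[g, s]
    count[g, s] ~ NB(mean = lib[s] * exp(log mu), dispersion alpha[g])

with ``f`` and ``eps`` standard normal. The latent term is mean-centred so
coupled and free genes have identical expected counts, and it is dropped
entirely when ``coupling == 0``, making such genes exactly negative binomial.
Before count noise, the TF-target correlation equals ``coupling``.

Planted DEGs are drawn module-targets-first (rewired regulation drives
expression change) and share a direction within a module; any remainder is
filled from free genes with random directions.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CountMatrix

logger = logging.getLogger(__name__)

_SEED_STREAMS = ("baseline", "dispersion", "library", "degs", "latent", "counts", "gene_sets")


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    # counter-based fan-out: each named stream is independent of call order
    idx = _SEED_STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)))


def _as_module_array(value, n_modules: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_modules,)).copy()
    if ((arr < 0) | (arr >= 1)).any():
        raise ValueError(f"{name} values must lie in [0, 1)")
    return arr


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults are the desk-scale study design
    (6 vs 6 samples, ~mean depth 1e6, 10 regulons among 2,000 genes)."""

    n_genes: int = 2000
    n_tfs: int = 100
    n_samples_per_condition: int = 6
    n_modules: int = 10
    module_size: int = 15
    coupling_a: float | Sequence[float] = 0.9
    coupling_b: float | Sequence[float] = 0.0
    frac_deg: float = 0.1
    lfc_range: tuple[float, float] = (0.5, 2.0)
    dispersion_shape: float = 2.0
    dispersion_rate: float = 40.0
    mean_log_mu: float = 5.5
    sd_log_mu: float = 1.5
    latent_sd: float = 0.7
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0
    levels: tuple[str, str] = ("CON", "VTM")

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tfs", "n_samples_per_condition", "n_modules", "module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_deg <= 1.0:
            raise ValueError("frac_deg must be in [0, 1]")
        if self.lfc_range[0] < 0 or self.lfc_range[1] < self.lfc_range[0]:
            raise ValueError("lfc_range must satisfy 0 <= min <= max")
        if self.dispersion_shape <= 0 or self.dispersion_rate <= 0:
            raise ValueError("dispersion shape/rate must be positive")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ValueError("lib_size_range must be positive and ordered")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be >= 0")
        if self.n_modules > self.n_tfs:
            raise ValueError("n_modules cannot exceed n_tfs")
        if self.n_tfs + self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"sizing error: {self.n_tfs} TFs + {self.n_modules}x{self.module_size} "
                f"module targets exceed {self.n_genes} genes"
            )
        _as_module_array(self.coupling_a, self.n_modules, "coupling_a")
        _as_module_array(self.coupling_b, self.n_modules, "coupling_b")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of one simulation (recovery oracle for downstream stages)."""

    gene_ids: list[str]
    tf_ids: list[str]
    deg_log2fc: pd.Series          # planted log2FC (treatment vs reference), DEGs only
    rewired_tf_ids: list[str]
    module_map: dict[str, list[str]]   # module TF -> target gene ids
    module_coupling: pd.DataFrame      # index = module TF, columns = [coupling_a, coupling_b]
    dispersion: pd.Series
    lib_factors: pd.Series

    @property
    def deg_ids(self) -> list[str]:
        return list(self.deg_log2fc.index)

    def up_module_tfs(self) -> list[str]:
        """Module TFs whose DEG targets were planted with a positive shift."""
        out = []
        for tf, targets in self.module_map.items():
            shifts = self.deg_log2fc.reindex(targets).dropna()
            if len(shifts) and (shifts > 0).all():
                out.append(tf)
        return out


def simulate_counts(params: SimulationParams) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one count matrix plus its ground truth. Identical seed, identical output."""
    p = params
    n_side = p.n_samples_per_condition
    ca = _as_module_array(p.coupling_a, p.n_modules, "coupling_a")
    cb = _as_module_array(p.coupling_b, p.n_modules, "coupling_b")

    width = max(4, len(str(p.n_genes)))
    tf_ids = [f"TF{i + 1:0{width}d}" for i in range(p.n_tfs)]
    other_ids = [f"G{i + 1:0{width}d}" for i in range(p.n_genes - p.n_tfs)]
    gene_ids = tf_ids + other_ids
    sample_ids = [f"{lev}_{i + 1}" for lev in p.levels for i in range(n_side)]
    conditions = pd.Series(
        [lev for lev in p.levels for _ in range(n_side)], index=sample_ids
    )

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    module_tfs = tf_ids[: p.n_modules]
    module_map: dict[str, list[str]] = {}
    cursor = 0
    for m, tf in enumerate(module_tfs):
        module_map[tf] = other_ids[cursor : cursor + p.module_size]
        cursor += p.module_size
    all_targets = [g for tgts in module_map.values() for g in tgts]
    free_genes = other_ids[cursor:]

    base = _child_rng(p.seed, "baseline").normal(p.mean_log_mu, p.sd_log_mu, p.n_genes)
    alpha = _child_rng(p.seed, "dispersion").gamma(
        p.dispersion_shape, 1.0 / p.dispersion_rate, p.n_genes
    )
    lib = _child_rng(p.seed, "library").uniform(*p.lib_size_range, 2 * n_side)

    # --- planted DEGs: module targets first, coherent sign per module -----
    deg_rng = _child_rng(p.seed, "degs")
    n_deg = int(round(p.frac_deg * p.n_genes))
    module_sign = deg_rng.choice([-1.0, 1.0], size=p.n_modules)
    candidates = list(deg_rng.permutation(all_targets)) + list(deg_rng.permutation(free_genes))
    chosen = candidates[:n_deg]
    target_module = {g: m for m, tgts in enumerate(module_map.values()) for g in tgts}
    signs = np.array(
        [
            module_sign[target_module[g]] if g in target_module else deg_rng.choice([-1.0, 1.0])
            for g in chosen
        ]
    )
    mags = deg_rng.uniform(p.lfc_range[0], p.lfc_range[1], size=len(chosen))
    deg_log2fc = pd.Series(signs * mags, index=pd.Index(chosen, name="gene"), name="log2fc")

    shift = np.zeros(p.n_genes)
    for g, fc in deg_log2fc.items():
        shift[gene_pos[g]] = fc * np.log(2.0)

    # --- latent module factors, condition-specific coupling ---------------
    latent_rng = _child_rng(p.seed, "latent")
    latent = np.zeros((p.n_genes, 2 * n_side))
    for cond_idx, coupling in enumerate((ca, cb)):
        cols = slice(cond_idx * n_side, (cond_idx + 1) * n_side)
        for m, tf in enumerate(module_tfs):
            f = latent_rng.normal(size=n_side)
            eps = latent_rng.normal(size=(p.module_size, n_side))
            c = coupling[m]
            if c == 0.0:
                continue  # decoupled module genes are exactly NB
            latent[gene_pos[tf], cols] = p.latent_sd * f - p.latent_sd**2 / 2.0
            tgt_rows = [gene_pos[g] for g in module_map[tf]]
            x = c * f[None, :] + np.sqrt(1.0 - c**2) * eps
            latent[tgt_rows, cols] = p.latent_sd * x - p.latent_sd**2 / 2.0

    is_b = np.array([1.0 if conditions[s] == p.levels[1] else 0.0 for s in sample_ids])
    log_mu = base[:, None] + shift[:, None] * is_b[None, :] + latent
    mu = lib[None, :] * np.exp(log_mu)

    count_rng = _child_rng(p.seed, "counts")
    counts = np.empty_like(mu, dtype=np.int64)
    poisson_like = alpha < 1e-8
    if poisson_like.any():
        counts[poisson_like] = count_rng.poisson(mu[poisson_like])
    if (~poisson_like).any():
        a = alpha[~poisson_like][:, None]
        m_ = mu[~poisson_like]
        counts[~poisson_like] = count_rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * m_))

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=sample_ids),
        conditions,
        p.levels,
    )
    rewired = [tf for m, tf in enumerate(module_tfs) if ca[m] != cb[m]]
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        tf_ids=tf_ids,
        deg_log2fc=deg_log2fc if n_deg else deg_log2fc.iloc[:0],
        rewired_tf_ids=rewired,
        module_map=module_map,
        module_coupling=pd.DataFrame(
            {"coupling_a": ca, "coupling_b": cb}, index=pd.Index(module_tfs, name="tf")
        ),
        dispersion=pd.Series(alpha, index=gene_ids, name="dispersion"),
        lib_factors=pd.Series(lib, index=sample_ids, name="lib_factor"),
    )
    logger.info(
        "simulated %d genes x %d samples: %d DEGs, %d rewired TFs",
        p.n_genes, 2 * n_side, len(deg_log2fc), len(rewired),
    )
    return cm, truth


def plant_gene_sets(
    truth: SyntheticTruth,
    n_random_sets: int = 0,
    set_size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> dict[str, list[str]]:
    """One "true" set per module (its targets) plus uniformly drawn decoys."""
    lo, hi = set_size_range
    if hi > len(truth.gene_ids):
        raise ValueError("set size exceeds number of genes")
    if lo < 1 or hi < lo:
        raise ValueError("set_size_range must satisfy 1 <= min <= max")
    sets = {f"module_{tf}": list(tgts) for tf, tgts in truth.module_map.items()}
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(len(_SEED_STREAMS) - 1,)))
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(truth.gene_ids, size=size, replace=False))
        sets[f"random_{i + 1:03d}"] = members
    return sets


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def desk_preset(seed: int = 0) -> SimulationParams:
    """Default desk-scale design mirroring a 6-vs-6 liver study at reduced width."""
    return SimulationParams(seed=seed)


def strong_signal_preset(seed: int = 0, rewired_modules: int | None = None) -> SimulationParams:
    """Recovery-benchmark design: 10 regulons of 50 targets, all targets planted
    as DEGs with |log2FC| = 2, tight dispersion, coupling 0.9 -> 0.0 in the
    treatment condition for the rewired modules."""
    n_modules = 10
    if rewired_modules is None:
        rewired_modules = n_modules
    cb = tuple(0.0 if m < rewired_modules else 0.9 for m in range(n_modules))
    return SimulationParams(
        n_genes=2000,
        n_tfs=100,
        n_modules=n_modules,
        module_size=50,
        coupling_a=0.9,
        coupling_b=cb,
        frac_deg=0.25,
        lfc_range=(2.0, 2.0),
        seed=seed,
    )
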