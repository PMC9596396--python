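"""Synthetic multi-histotype, multi-case, multi-region expression data.

The generator emulates the variance structure of multi-region tumor
sampling on the log2 scale. Each gene ``g`` in sample ``s`` is drawn as

    x[g,s] = baseline_mean + b[g] + h[g, H(s)] + c[g, C(s)]
             + sum_m lambda[g,m] * f[m,s] + eps[g,s]
             + delta * 1{g in a planted set targeting s}

with independent Gaussian components: a per-gene baseline ``b``
(sd ``baseline_sd``), a per-(gene, histotype) shift ``h`` (sd
``histotype_sd``), a per-(gene, case) shift ``c`` (sd ``case_sd`` of the
case's histotype), latent-factor co-expression modules (per-sample factor
``f``, per-gene loadings ``lambda``), and within-case noise ``eps`` (sd
``sample_sd`` of the case's histotype). Planted gene sets add a fixed mean
shift ``delta`` to their member genes in the targeted histotypes, cases or
samples; this is the signal the single-sample z-score statistic is designed
to detect.

Randomness is organised as one child stream per variance component
(spawned from a single seed), so adding a planted module to a configuration
does not perturb the baseline, group-shift or noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSetCollection

__all__ = [
    "HistotypeSpec",
    "PlantedSet",
    "PlantedModule",
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "default_study_config",
    "set_recovery_config",
    "module_recovery_config",
]


@dataclass(frozen=True)
class HistotypeSpec:
    """Design of one histotype: cases, samples per case, and its noise scales."""

    name: str
    n_cases: int
    samples_per_case: int | tuple[int, ...]
    case_sd: float
    sample_sd: float

    def case_sizes(self) -> list[int]:
        if isinstance(self.samples_per_case, int):
            return [self.samples_per_case] * self.n_cases
        sizes = list(self.samples_per_case)
        if len(sizes) != self.n_cases:
            raise ValueError(
                f"histotype {self.name!r}: {len(sizes)} sample counts for "
                f"{self.n_cases} cases"
            )
        return sizes


@dataclass(frozen=True)
class PlantedSet:
    """A gene set whose members get a mean shift in the targeted groups.

    ``scope`` is ``'histotype'``, ``'case'`` or ``'sample'``; ``targets``
    are labels at that scope. ``shift`` is in log2 units and may be negative.
    """

    name: str
    n_genes: int
    scope: str
    targets: tuple[str, ...]
    shift: float


@dataclass(frozen=True)
class PlantedModule:
    """A latent-factor co-expression module.

    Member genes load on a shared per-sample factor ``f ~ N(0, factor_sd^2)``
    with loadings drawn uniformly from ``loading_range`` (all positive by
    default, so the module is coherent under unsigned correlation). Setting
    ``correlated_with``/``factor_correlation`` makes this module's factor
    correlate with an earlier module's factor, which is how eigengene-level
    module merging scenarios are constructed.
    """

    name: str
    n_genes: int
    factor_sd: float = 1.0
    loading_range: tuple[float, float] = (0.5, 1.0)
    correlated_with: str | None = None
    factor_correlation: float = 0.0


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    histotypes: tuple[HistotypeSpec, ...] = ()
    histotype_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    planted_sets: tuple[PlantedSet, ...] = ()
    planted_modules: tuple[PlantedModule, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not self.histotypes:
            raise ValueError("at least one histotype is required")
        for sd_name in ("histotype_sd", "baseline_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        for h in self.histotypes:
            if h.case_sd < 0 or h.sample_sd < 0:
                raise ValueError(f"histotype {h.name!r}: sds must be >= 0")
            h.case_sizes()
        n_planted = sum(s.n_genes for s in self.planted_sets) + sum(
            m.n_genes for m in self.planted_modules
        )
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted sets/modules need {n_planted} genes but n_genes={self.n_genes}"
            )
        names = [s.name for s in self.planted_sets] + [
            m.name for m in self.planted_modules
        ]
        if len(set(names)) != len(names):
            raise ValueError("planted set/module names must be unique")
        module_names = set()
        for m in self.planted_modules:
            if m.correlated_with is not None:
                if m.correlated_with not in module_names:
                    raise ValueError(
                        f"module {m.name!r}: correlated_with must name an earlier module"
                    )
                if not -1.0 <= m.factor_correlation <= 1.0:
                    raise ValueError("factor_correlation must be in [-1, 1]")
            module_names.add(m.name)

    @property
    def total_samples(self) -> int:
        return sum(sum(h.case_sizes()) for h in self.histotypes)

    @property
    def total_cases(self) -> int:
        return sum(h.n_cases for h in self.histotypes)

    # -- (de)serialisation for the CLI ----------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["histotypes"] = [asdict(h) for h in self.histotypes]
        d["planted_sets"] = [asdict(s) for s in self.planted_sets]
        d["planted_modules"] = [asdict(m) for m in self.planted_modules]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["histotypes"] = tuple(
            HistotypeSpec(
                **{
                    **h,
                    "samples_per_case": (
                        tuple(h["samples_per_case"])
                        if isinstance(h["samples_per_case"], (list, tuple))
                        else h["samples_per_case"]
                    ),
                }
            )
            for h in d.get("histotypes", ())
        )
        d["planted_sets"] = tuple(
            PlantedSet(**{**s, "targets": tuple(s["targets"])})
            for s in d.get("planted_sets", ())
        )
        d["planted_modules"] = tuple(
            PlantedModule(**{**m, "loading_range": tuple(m["loading_range"])})
            for m in d.get("planted_modules", ())
        )
        return cls(**d)


@dataclass
class GroundTruth:
    """What was planted: memberships, targets, factors and noise scales."""

    set_members: dict[str, list[str]]
    set_targets: dict[str, PlantedSet]
    module_members: dict[str, list[str]]
    module_loadings: dict[str, pd.Series]
    module_factors: pd.DataFrame  # samples x modules
    histotype_sd: float
    case_sd: dict[str, float]
    sample_sd: dict[str, float]


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for h in config.histotypes:
        for ci, size in enumerate(h.case_sizes(), start=1):
            case_id = f"{h.name}_c{ci}"
            for si in range(1, size + 1):
                rows.append((f"{case_id}_s{si}", case_id, h.name))
    table = pd.DataFrame(rows, columns=["sample_id", "case_id", "histotype"])
    return table.set_index("sample_id")


def generate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ExpressionDataset, GeneSetCollection, GroundTruth]:
    """Draw one dataset from ``config``; returns (dataset, planted GMT, truth).

    Reproducible: the same config and seed give bit-identical output.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(int(seed))
    s_base, s_hist, s_case, s_module, s_noise = ss.spawn(5)
    rng_base = np.random.default_rng(s_base)
    rng_hist = np.random.default_rng(s_hist)
    rng_case = np.random.default_rng(s_case)
    rng_noise = np.random.default_rng(s_noise)

    ann = _sample_table(config)
    sample_ids = ann.index
    n_samples = len(sample_ids)
    n_genes = config.n_genes
    width = max(4, len(str(n_genes)))
    gene_ids = pd.Index([f"G{i:0{width}d}" for i in range(1, n_genes + 1)], name="gene_id")

    # deterministic, disjoint gene pools: planted sets first, then modules
    cursor = 0
    set_members: dict[str, list[str]] = {}
    for pset in config.planted_sets:
        set_members[pset.name] = list(gene_ids[cursor : cursor + pset.n_genes])
        cursor += pset.n_genes
    module_members: dict[str, list[str]] = {}
    for mod in config.planted_modules:
        module_members[mod.name] = list(gene_ids[cursor : cursor + mod.n_genes])
        cursor += mod.n_genes

    hist_names = [h.name for h in config.histotypes]
    hist_of = {h.name: h for h in config.histotypes}

    x = np.full((n_genes, n_samples), float(config.baseline_mean))
    x += rng_base.normal(0.0, config.baseline_sd, size=(n_genes, 1))

    h_shift = rng_hist.normal(0.0, config.histotype_sd, size=(n_genes, len(hist_names)))
    hist_col = ann["histotype"].map({name: i for i, name in enumerate(hist_names)})
    x += h_shift[:, hist_col.to_numpy()]

    case_ids = ann["case_id"]
    for case in case_ids.unique():
        members = (case_ids == case).to_numpy()
        spec = hist_of[ann.loc[members, "histotype"].iloc[0]]
        c_shift = rng_case.normal(0.0, spec.case_sd, size=n_genes)
        x[:, members] += c_shift[:, None]
        x[:, members] += rng_noise.normal(
            0.0, spec.sample_sd, size=(n_genes, int(members.sum()))
        )

    # latent-factor modules (one child stream per module)
    factors = pd.DataFrame(index=sample_ids, dtype=float)
    loadings: dict[str, pd.Series] = {}
    module_streams = s_module.spawn(max(1, len(config.planted_modules)))
    for mod, child in zip(config.planted_modules, module_streams):
        rng_m = np.random.default_rng(child)
        lo, hi = mod.loading_range
        lam = rng_m.uniform(lo, hi, size=mod.n_genes)
        z = rng_m.normal(0.0, 1.0, size=n_samples)
        if mod.correlated_with is not None:
            rho = mod.factor_correlation
            ref = factors[mod.correlated_with].to_numpy()
            ref_spec = next(
                m for m in config.planted_modules if m.name == mod.correlated_with
            )
            ref_std = ref / ref_spec.factor_sd if ref_spec.factor_sd > 0 else ref
            f = mod.factor_sd * (rho * ref_std + np.sqrt(max(0.0, 1 - rho**2)) * z)
        else:
            f = mod.factor_sd * z
        factors[mod.name] = f
        idx = gene_ids.get_indexer(module_members[mod.name])
        x[idx, :] += np.outer(lam, f)
        loadings[mod.name] = pd.Series(lam, index=module_members[mod.name])

    # planted mean shifts
    for pset in config.planted_sets:
        if pset.scope == "histotype":
            mask = ann["histotype"].isin(pset.targets).to_numpy()
        elif pset.scope == "case":
            mask = ann["case_id"].isin(pset.targets).to_numpy()
        elif pset.scope == "sample":
            mask = sample_ids.isin(pset.targets)
        else:
            raise ValueError(f"planted set {pset.name!r}: unknown scope {pset.scope!r}")
        if not mask.any():
            raise ValueError(
                f"planted set {pset.name!r}: no sample matches targets {pset.targets}"
            )
        idx = gene_ids.get_indexer(set_members[pset.name])
        x[np.ix_(idx, np.flatnonzero(mask))] += pset.shift

    values = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    dataset = ExpressionDataset(values, ann.copy())
    gmt = GeneSetCollection(
        {name: list(members) for name, members in set_members.items()},
        {p.name: f"planted {p.scope} shift {p.shift:+g}" for p in config.planted_sets},
    )
    truth = GroundTruth(
        set_members=set_members,
        set_targets={p.name: p for p in config.planted_sets},
        module_members=module_members,
        module_loadings=loadings,
        module_factors=factors,
        histotype_sd=config.histotype_sd,
        case_sd={h.name: h.case_sd for h in config.histotypes},
        sample_sd={h.name: h.sample_sd for h in config.histotypes},
    )
    return dataset, gmt, truth


# ---------------------------------------------------------------------------
# canonical configurations
# ---------------------------------------------------------------------------

def default_study_config(seed: int = 0) -> SimulationConfig:
    """The multi-region pediatric-tumor design: 4 histotypes x 5 cases, 79 samples.

    Five cases per histotype with four FFPE-block samples each, except one
    neuroblastoma case with only three blocks (79 samples in total).
    Histotype-level shifts (sd 1.0) dominate case-level shifts (sd 0.5),
    which dominate within-case noise; within-case noise is ordered
    NB > HB = RMS > WT, neuroblastoma being the most and Wilms tumor the
    least heterogeneous histotype. A handful of gene sets are planted at
    histotype, case and sample granularity (shift +1.0 log2), and three
    weak latent-factor modules provide co-expression structure.
    """
    histotypes = (
        HistotypeSpec("HB", 5, 4, case_sd=0.5, sample_sd=0.5),
        HistotypeSpec("NB", 5, (4, 4, 4, 4, 3), case_sd=0.5, sample_sd=0.9),
        HistotypeSpec("RMS", 5, 4, case_sd=0.5, sample_sd=0.5),
        HistotypeSpec("WT", 5, 4, case_sd=0.5, sample_sd=0.2),
    )
    planted_sets = (
        PlantedSet("SET_HB_UP", 30, "histotype", ("HB",), 1.0),
        PlantedSet("SET_NB_UP", 30, "histotype", ("NB",), 1.0),
        PlantedSet("SET_WT_RMS_UP", 30, "histotype", ("WT", "RMS"), 1.0),
        PlantedSet("SET_HB_CASE1_UP", 30, "case", ("HB_c1",), 1.0),
        PlantedSet("SET_ONE_SAMPLE_UP", 20, "sample", ("HB_c2_s1",), 1.0),
    )
    planted_modules = (
        PlantedModule("MOD_A", 30, factor_sd=0.6),
        PlantedModule("MOD_B", 30, factor_sd=0.6),
        PlantedModule("MOD_C", 30, factor_sd=0.6),
    )
    return SimulationConfig(
        n_genes=2000,
        histotypes=histotypes,
        histotype_sd=1.0,
        baseline_mean=6.0,
        baseline_sd=1.0,
        planted_sets=planted_sets,
        planted_modules=planted_modules,
        seed=seed,
    )


def set_recovery_config(seed: int = 0, shift: float = 1.0) -> SimulationConfig:
    """Planted-enrichment recovery scenario on the 79-sample design.

    A 30-gene set is shifted by ``shift`` log2 units in every sample of one
    histotype (HB), and a second set in two histotypes (WT and RMS) for
    shared-pathway detection. Background group shifts are kept moderate
    (histotype sd 0.5, case sd 0.3, within-case sd 0.3) so the planted
    location shift is the dominant set-level signal.
    """
    histotypes = tuple(
        HistotypeSpec(name, 5, (4, 4, 4, 4, 3) if name == "NB" else 4, 0.3, 0.3)
        for name in ("HB", "NB", "RMS", "WT")
    )
    planted_sets = (
        PlantedSet("SET_TARGET", 30, "histotype", ("HB",), shift),
        PlantedSet("SET_SHARED", 30, "histotype", ("WT", "RMS"), shift),
    )
    return SimulationConfig(
        n_genes=800,
        histotypes=histotypes,
        histotype_sd=0.5,
        baseline_mean=6.0,
        baseline_sd=1.0,
        planted_sets=planted_sets,
        seed=seed,
    )


def module_recovery_config(
    seed: int = 0,
    n_modules: int = 3,
    module_size: int = 40,
    correlated_pair: bool = False,
) -> SimulationConfig:
    """Latent-module recovery scenario: modules plus iid noise, one histotype.

    ``n_modules`` disjoint modules of ``module_size`` genes (loadings
    uniform on [0.5, 1.0], factor sd 1.5) against a 300-gene background with
    within-case noise sd 0.5 and no histotype/case shifts, over 60 samples.
    With ``correlated_pair`` the last module's factor correlates at 0.9 with
    the previous one, so their eigengenes should be merged.
    """
    modules = []
    for i in range(n_modules):
        name = f"MOD_{chr(ord('A') + i)}"
        if correlated_pair and i == n_modules - 1 and n_modules >= 2:
            modules.append(
                PlantedModule(
                    name,
                    module_size,
                    factor_sd=1.5,
                    correlated_with=f"MOD_{chr(ord('A') + i - 1)}",
                    factor_correlation=0.9,
                )
            )
        else:
            modules.append(PlantedModule(name, module_size, factor_sd=1.5))
    return SimulationConfig(
        n_genes=300,
        histotypes=(HistotypeSpec("T", 15, 4, case_sd=0.0, sample_sd=0.5),),
        histotype_sd=0.0,
        baseline_mean=6.0,
        baseline_sd=1.0,
        planted_modules=tuple(modules),
        seed=seed,
    )
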