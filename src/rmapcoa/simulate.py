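"""Generative scenarios for repeated-measures microbiome studies.

Three study designs exercise every stage of the adjustment pipeline:

1. **Time-invariant nuisance** (``scenario_time_invariant``): n subjects, m
   visits. A baseline community per subject is a Dirichlet perturbation of a
   seed sample; later visits evolve by multinomial resampling with
   Dirichlet-smoothed probabilities (library size carried forward exactly).
   From the first post-baseline visit, 20 taxa shared by everyone are scaled
   by 0.25, 20 treatment taxa by 3 in the treated arm, and 20
   prevalence-spanning taxa by 8 in females — the large sex effect obscures
   the treatment signal unless adjusted away.
2. **Time-varying nuisance** (``scenario_time_varying``): as above, but the
   obscuring covariate is a sickness indicator redrawn Bernoulli(1/2) at
   every visit (including baseline), scaling its taxa by 24 while sick.
3. **Clustered design** (``scenario_clustered``): n families of 3 members,
   no time axis. Members 2 and 3 are drawn per taxon from a bivariate normal
   centred at member 1's count; treatments scale 20 taxa by 8 (member 2) and
   32 (member 3). Family membership is the nuisance clustering.

Counts are kept real-valued while effects compound and rounded to whole
reads once a scenario finishes (negatives truncated to zero in scenario 3).
Effect taxa sets never overlap. The baseline seed table defaults to a fully
synthetic sparse community matrix at the scale of a real vaginal 16S survey
(270 samples x 233 OTUs, log-normal library sizes, heavy-tailed Dirichlet
compositions); a real table can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .kernels import AbundanceTable
from .mixed_adjust import SampleDesign

__all__ = [
    "ScenarioConfig",
    "SimulatedStudy",
    "synthetic_baseline",
    "dirichlet_perturb",
    "evolve_timepoint",
    "apply_multiplicative_effect",
    "select_prevalence_spanning_taxa",
    "scenario_time_invariant",
    "scenario_time_varying",
    "scenario_clustered",
]

#: prevalence grid spanned by the sex/sickness effect taxa
PREVALENCE_TARGETS = np.arange(0.0, 1.0, 0.1)


@dataclass
class ScenarioConfig:
    """Knobs of the generative scenarios; defaults are the study conditions.

    ``multipliers`` hold the fold-changes applied to each effect-taxa set:
    shared 0.25, treatment 3, sex 8, sickness 24, and for the clustered
    design member-2 8 and member-3 32. ``family_cov`` is the 2x2 covariance
    of the bivariate normal tying members 2 and 3 to member 1 (the default
    compound-symmetric [[17, 10], [10, 17]] is a documented stand-in; the
    value could not be sourced reliably).
    """

    n_subjects: int = 100
    n_timepoints: int = 4
    n_taxa: int = 233
    n_effect_taxa: int = 20
    pseudocount: float = 0.5
    seed: int = 0
    multipliers: dict = field(
        default_factory=lambda: {
            "shared": 0.25,
            "treatment": 3.0,
            "sex": 8.0,
            "sickness": 24.0,
            "member2": 8.0,
            "member3": 32.0,
        }
    )
    baseline: Optional[AbundanceTable] = None
    baseline_pool_size: int = 270
    family_cov: np.ndarray = field(
        default_factory=lambda: np.array([[17.0, 10.0], [10.0, 17.0]])
    )

    def __post_init__(self):
        if min(self.n_subjects, self.n_timepoints, self.n_taxa) <= 0:
            raise ValueError("n_subjects, n_timepoints and n_taxa must be positive")
        if any(v <= 0 for v in self.multipliers.values()):
            raise ValueError("multipliers must be positive")
        cov = np.asarray(self.family_cov, dtype=float)
        if cov.shape != (2, 2) or np.abs(cov - cov.T).max() > 1e-12:
            raise ValueError("family_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(cov).min() < 0:
            raise ValueError("family_cov must be positive semidefinite")
        self.family_cov = cov


@dataclass
class SimulatedStudy:
    """A generated count table, its sample design, and the ground truth used."""

    table: AbundanceTable
    design: SampleDesign
    truth: dict


def synthetic_baseline(
    n: int,
    p: int,
    seed: int | np.random.Generator = 0,
    median_library: float = 1e4,
    library_sigma: float = 0.7,
    concentration: float = 0.25,
    tail_sigma: float = 2.0,
) -> AbundanceTable:
    """Fully synthetic sparse baseline community table.

    Library sizes are log-normal (median ``median_library``); sample
    compositions are Dirichlet draws around a global heavy-tailed
    (log-normal, ``tail_sigma``) taxon profile with small per-taxon
    ``concentration``, so multinomial sampling produces realistic sparsity:
    most taxa absent from most samples, a few dominant ones.
    """
    if n <= 0 or p <= 0:
        raise ValueError("n and p must be positive")
    rng = np.random.default_rng(seed)
    weights = rng.lognormal(0.0, tail_sigma, size=p)
    alpha = concentration * p * weights / weights.sum()
    libs = np.rint(rng.lognormal(np.log(median_library), library_sigma, size=n))
    libs = np.maximum(libs, 100).astype(int)
    counts = np.empty((n, p), dtype=float)
    for i in range(n):
        probs = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(libs[i], probs)
    return AbundanceTable(
        counts,
        [f"baseline{i:03d}" for i in range(n)],
        [f"OTU{k:03d}" for k in range(p)],
    )


def dirichlet_perturb(
    row: np.ndarray, pseudocount: float = 0.5, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Perturb a count vector: draw Dirichlet(row + pseudocount) and rescale
    by the row's library size (preserved up to rounding)."""
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise ValueError("counts must be nonnegative")
    if pseudocount <= 0 and row.sum() == 0:
        raise ValueError("all-zero row requires a positive pseudocount")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(row + pseudocount)
    return np.rint(probs * row.sum())


def evolve_timepoint(
    prev_row: np.ndarray, pseudocount: float = 0.5, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One step of community evolution: multinomial with the previous library
    size as trials and Dirichlet(prev + pseudocount) probabilities. The output
    total equals the previous library size exactly."""
    prev_row = np.asarray(prev_row, dtype=float)
    total = int(np.rint(prev_row.sum()))
    if total <= 0:
        raise ValueError("previous row must have positive total count")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(prev_row + pseudocount)
    return rng.multinomial(total, probs).astype(float)


def apply_multiplicative_effect(
    counts: np.ndarray, taxa_set: np.ndarray, factor: float, sample_mask=None
) -> np.ndarray:
    """Scale the given taxa by ``factor`` for the masked samples (all if None)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    counts = np.array(counts, dtype=float, copy=True)
    taxa_set = np.asarray(taxa_set, dtype=int)
    if taxa_set.size and (taxa_set.min() < 0 or taxa_set.max() >= counts.shape[-1]):
        raise ValueError("taxa_set indices out of range")
    if counts.ndim == 1:
        counts[taxa_set] *= factor
        return counts
    if sample_mask is None:
        counts[:, taxa_set] *= factor
    else:
        sample_mask = np.asarray(sample_mask, dtype=bool)
        counts[np.ix_(sample_mask, taxa_set)] *= factor
    return counts


def select_prevalence_spanning_taxa(
    table: AbundanceTable | np.ndarray, exclude=(),
) -> np.ndarray:
    """Pick pairs of taxa with observed prevalence closest to each of
    0, 0.1, ..., 0.9 (20 taxa; ties and reuse resolved toward lower index)."""
    counts = table.counts if isinstance(table, AbundanceTable) else np.asarray(table)
    p = counts.shape[1]
    exclude = set(int(i) for i in exclude)
    if p - len(exclude) < 2 * len(PREVALENCE_TARGETS):
        raise ValueError(
            f"need at least {2 * len(PREVALENCE_TARGETS)} selectable taxa, "
            f"have {p - len(exclude)}"
        )
    prevalence = (counts > 0).mean(axis=0)
    chosen: list[int] = []
    taken = set(exclude)
    for target in PREVALENCE_TARGETS:
        gaps = np.abs(prevalence - target)
        # two best per target; argsort is stable so ties break toward lower index
        for idx in np.argsort(gaps, kind="stable"):
            if int(idx) not in taken:
                chosen.append(int(idx))
                taken.add(int(idx))
                if len(chosen) % 2 == 0:
                    break
    return np.array(sorted(chosen), dtype=int)


def _draw_disjoint_sets(rng, p, sizes, reserved=()):
    """Random disjoint taxa index sets of the given sizes."""
    available = np.setdiff1d(np.arange(p), np.asarray(list(reserved), dtype=int))
    need = sum(sizes)
    if len(available) < need:
        raise ValueError(f"not enough taxa ({len(available)}) for {need} effect slots")
    picks = rng.choice(available, size=need, replace=False)
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(picks[start : start + s]))
        start += s
    return out


def _check_disjoint(sets: dict) -> None:
    flat = np.concatenate([np.asarray(v) for v in sets.values() if len(v)])
    if len(flat) != len(np.unique(flat)):
        raise ValueError("effect taxa sets overlap")


def _baseline_pool(config: ScenarioConfig, rng) -> AbundanceTable:
    if config.baseline is not None:
        if config.baseline.n_taxa < config.n_taxa:
            raise ValueError("supplied baseline has fewer taxa than n_taxa")
        return config.baseline
    return synthetic_baseline(
        max(config.baseline_pool_size, config.n_subjects), config.n_taxa, rng
    )


def _longitudinal_scenario(config: ScenarioConfig, time_varying: bool) -> SimulatedStudy:
    rng = np.random.default_rng(config.seed)
    n, m, p = config.n_subjects, config.n_timepoints, config.n_taxa
    pc = config.pseudocount
    mult = config.multipliers
    pool = _baseline_pool(config, rng)

    arm = rng.integers(0, 2, size=n)  # 1 = treated
    if time_varying:
        sickness = rng.integers(0, 2, size=(n, m))
    else:
        sex = rng.integers(0, 2, size=n)  # 1 = female

    # effect taxa: the obscuring covariate's 20 taxa span the prevalence grid
    # (computed on the seed pool); shared & treatment sets are random draws.
    nuisance_set = select_prevalence_spanning_taxa(pool)
    shared_set, treatment_set = _draw_disjoint_sets(
        rng, p, [config.n_effect_taxa, config.n_effect_taxa], reserved=nuisance_set
    )
    nuisance_name = "sickness" if time_varying else "sex"
    sets = {
        "shared": shared_set,
        "treatment": treatment_set,
        nuisance_name: nuisance_set,
    }
    _check_disjoint(sets)

    pool_rows = rng.choice(pool.n_samples, size=n, replace=False)
    streams = rng.spawn(n)
    counts = np.empty((n, m, p), dtype=float)
    for i, sub_rng in enumerate(streams):
        y = dirichlet_perturb(pool.counts[pool_rows[i]], pc, sub_rng)
        if time_varying and sickness[i, 0]:
            y = apply_multiplicative_effect(y, nuisance_set, mult["sickness"])
        counts[i, 0] = y
        for j in range(1, m):
            y = evolve_timepoint(counts[i, j - 1], pc, sub_rng)
            y = apply_multiplicative_effect(y, shared_set, mult["shared"])
            if arm[i]:
                y = apply_multiplicative_effect(y, treatment_set, mult["treatment"])
            if time_varying:
                if sickness[i, j]:
                    y = apply_multiplicative_effect(y, nuisance_set, mult["sickness"])
            elif sex[i]:
                y = apply_multiplicative_effect(y, nuisance_set, mult["sex"])
            counts[i, j] = y
    counts = np.rint(counts)

    sample_ids = [f"S{i:03d}_t{j}" for i in range(n) for j in range(m)]
    meta = {
        "subject": [f"S{i:03d}" for i in range(n) for _ in range(m)],
        "time": [j for _ in range(n) for j in range(m)],
        "arm": ["treatment" if arm[i] else "control" for i in range(n) for _ in range(m)],
    }
    if time_varying:
        meta["sickness"] = [
            "sick" if sickness[i, j] else "well" for i in range(n) for j in range(m)
        ]
    else:
        meta["sex"] = ["F" if sex[i] else "M" for i in range(n) for _ in range(m)]
    metadata = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))
    table = AbundanceTable(counts.reshape(n * m, p), sample_ids, pool.taxon_ids[:p])
    design = SampleDesign(metadata, subject_col="subject", time_col="time")
    truth = {
        "scenario": "time_varying" if time_varying else "time_invariant",
        "effect_taxa": {k: v.tolist() for k, v in sets.items()},
        "multipliers": {
            "shared": mult["shared"],
            "treatment": mult["treatment"],
            nuisance_name: mult["sickness" if time_varying else "sex"],
        },
        "arm": ["treatment" if a else "control" for a in arm],
    }
    if time_varying:
        truth["sickness"] = sickness.tolist()
    else:
        truth["sex"] = ["F" if s else "M" for s in sex]
    return SimulatedStudy(table, design, truth)


def scenario_time_invariant(config: ScenarioConfig) -> SimulatedStudy:
    """Treatment effect obscured by a large time-invariant sex effect."""
    return _longitudinal_scenario(config, time_varying=False)


def scenario_time_varying(config: ScenarioConfig) -> SimulatedStudy:
    """Treatment effect obscured by a time-varying sickness status."""
    return _longitudinal_scenario(config, time_varying=True)


def scenario_clustered(config: ScenarioConfig) -> SimulatedStudy:
    """Family-clustered design: three members per family, member-specific
    treatments, within-family similarity as the nuisance structure."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_taxa
    m = 3
    pc = config.pseudocount
    mult = config.multipliers
    pool = _baseline_pool(config, rng)

    member2_set, member3_set = _draw_disjoint_sets(
        rng, p, [config.n_effect_taxa, config.n_effect_taxa]
    )
    _check_disjoint({"member2": member2_set, "member3": member3_set})

    pool_rows = rng.choice(pool.n_samples, size=n, replace=False)
    streams = rng.spawn(n)
    counts = np.empty((n, m, p), dtype=float)
    for i, sub_rng in enumerate(streams):
        y1 = dirichlet_perturb(pool.counts[pool_rows[i]], pc, sub_rng)
        # members 2 and 3 jointly normal around member 1, taxon by taxon
        noise = sub_rng.multivariate_normal(np.zeros(2), config.family_cov, size=p)
        y2 = y1 + noise[:, 0]
        y3 = y1 + noise[:, 1]
        y2 = apply_multiplicative_effect(y2, member2_set, mult["member2"])
        y3 = apply_multiplicative_effect(y3, member3_set, mult["member3"])
        counts[i, 0], counts[i, 1], counts[i, 2] = y1, y2, y3
    counts = np.clip(np.rint(counts), 0.0, None)

    sample_ids = [f"F{i:03d}_m{j + 1}" for i in range(n) for j in range(m)]
    metadata = pd.DataFrame(
        {
            "family": [f"F{i:03d}" for i in range(n) for _ in range(m)],
            "member": [j + 1 for _ in range(n) for j in range(m)],
            "arm": [f"treatment{j + 1}" for _ in range(n) for j in range(m)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = AbundanceTable(counts.reshape(n * m, p), sample_ids, pool.taxon_ids[:p])
    design = SampleDesign(metadata, subject_col="family", time_col=None)
    truth = {
        "scenario": "clustered",
        "effect_taxa": {
            "member2": member2_set.tolist(),
            "member3": member3_set.tolist(),
        },
        "multipliers": {"member2": mult["member2"], "member3": mult["member3"]},
        "family_cov": config.family_cov.tolist(),
    }
    return SimulatedStudy(table, design, truth)
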