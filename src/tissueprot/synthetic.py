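"""Synthetic multi-tissue proteomics cohorts with recorded ground truth.

Generates everything the downstream pipeline consumes — sample metadata,
per-tissue log2 intensity matrices with planted group and covariate effects,
left-censored (MNAR) missingness, gene-set collections, and ambiguous
identifier lists — while recording the exact generative truth so recovery can
be measured.

The generative model per protein p, subject i, tissue t:

    y_pit = mu_p + b_pi + delta_p * 1[group_i affected] +
            sum_c beta_pc * (x_ci - mean(x_c)) + eps_pit

with protein baseline ``mu_p ~ Uniform(baseline_mu_range)``, a subject-level
deviation ``b_pi ~ N(0, baseline_sd)`` shared across tissues (subjects carry
their proteome between organs; tissue effects are then tissue-specific), and
residual ``eps ~ N(0, residual_sd)``, all on the log2 scale. Missingness is
probit left-censoring around a per-sample detection threshold, emulating the
strong low-abundance bias of label-free MS data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection, IntensityMatrix, write_gmt
from .ids import IdentifierRecord

__all__ = [
    "CohortSpec",
    "SignalSpec",
    "CensorSpec",
    "TruthRecord",
    "generate_cohort",
    "generate_proteome",
    "apply_missingness",
    "generate_gene_sets",
    "generate_identifier_lists",
]

GROUPS = ("CTRL", "PD", "T2D")

#: Study-like defaults: five metabolic tissues; islet purity exists only there.
DEFAULT_TISSUES = ("islets", "liver", "muscle", "vat", "serum")
ISLET_TISSUE = "islets"

#: Per-covariate sampling distributions on their natural scales:
#: BMI kg/m2, age years, cold ischemic time (CIT) hours, ICU stay days,
#: islet purity percent.
DEFAULT_COVARIATE_PARAMS: dict[str, tuple] = {
    "BMI": ("normal", 27.0, 4.0),
    "age": ("normal", 55.0, 10.0),
    "CIT": ("normal", 9.0, 3.0),
    "ICU_days": ("poisson1", 3.0),
    "purity": ("normal", 70.0, 10.0),
}

#: Group-conditional trait distributions: HbA1c (%) rises and glucose-
#: stimulated insulin secretion (GSIS, stimulation index) falls along
#: CTRL -> PD -> T2D.
TRAIT_PARAMS = {
    "HbA1c": {"CTRL": (5.3, 0.25), "PD": (6.0, 0.25), "T2D": (7.6, 1.0)},
    "GSIS": {"CTRL": (20.0, 5.0), "PD": (14.0, 5.0), "T2D": (8.0, 4.0)},
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: group sizes, tissues, covariate distributions, seed."""

    n_per_group: tuple[int, int, int] = (17, 14, 12)
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    covariate_params: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_group) != len(GROUPS):
            raise ValueError("n_per_group: need one count per group (CTRL, PD, T2D)")
        for group, n in zip(GROUPS, self.n_per_group):
            if n < 2:
                raise ValueError(f"n_per_group[{group}]: counts must be >= 2, got {n}")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissues: names must be unique")


@dataclass(frozen=True)
class SignalSpec:
    """Planted effects: (set name, per-protein log2 shift, affected group)
    triples, per-covariate (slope, affected fraction) pairs, and the scale of
    the baseline proteome."""

    planted_sets: tuple[tuple[str, float, str], ...] = ()
    covariate_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"BMI": (0.03, 1.0), "age": (0.012, 1.0)}
    )
    baseline_mu_range: tuple[float, float] = (18.0, 30.0)
    baseline_sd: float = 0.3
    residual_sd: float = 0.8

    def validate(self, sets: GeneSetCollection) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        for set_name, delta, group in self.planted_sets:
            if set_name not in sets:
                raise ValueError(f"planted set {set_name!r} absent from collection")
            if not np.isfinite(delta):
                raise ValueError(f"planted set {set_name!r}: delta must be finite")
            if group not in GROUPS:
                raise ValueError(f"planted set {set_name!r}: unknown group {group!r}")


@dataclass(frozen=True)
class CensorSpec:
    """Left-censoring model.

    ``P(missing | value v) = Phi(s * (T_sample - v)) + mcar_rate`` (clipped to
    [0, 1]) where ``T_sample`` is the ``censor_quantile`` quantile of that
    sample's complete values and ``s = censor_steepness`` is the probit slope
    (per log2 unit; ``inf`` gives a hard detection limit).
    """

    censor_quantile: float = 0.15
    censor_steepness: float = 2.0
    mcar_rate: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.censor_quantile < 1:
            raise ValueError("censor_quantile must be in [0, 1)")
        if not 0 <= self.mcar_rate <= 0.2:
            raise ValueError("mcar_rate must be in [0, 0.2]")
        if self.censor_steepness <= 0:
            raise ValueError("censor_steepness must be > 0 (inf allowed)")


@dataclass
class TruthRecord:
    """Exact generative truth for one synthetic proteome."""

    #: per-protein additive shift for each group (0 where unaffected)
    group_shift: pd.DataFrame
    #: per-protein slope for each covariate (0 where unaffected)
    covariate_slopes: pd.DataFrame
    #: set name -> (delta, affected group)
    planted_sets: dict[str, tuple[float, str]]
    #: (tissue, sample) -> censoring threshold, filled by apply_missingness
    censor_thresholds: dict[str, dict[str, float]] = field(default_factory=dict)

    def true_logfc(self, group_a: Sequence[str], group_b: Sequence[str],
                   n_per_group: Mapping[str, int] | None = None) -> pd.Series:
        """Per-protein true log2 fold change for contrast B vs A.

        Merged groups are weighted by their sample counts, matching the OLS
        estimand of a pooled group indicator.
        """
        def pooled(groups: Sequence[str]) -> pd.Series:
            if n_per_group is None:
                w = np.ones(len(groups))
            else:
                w = np.array([n_per_group[g] for g in groups], dtype=float)
            w = w / w.sum()
            return sum(wi * self.group_shift[g] for wi, g in zip(w, groups))

        return pooled(group_b) - pooled(group_a)

    def enriched_sets(self) -> dict[str, tuple[float, str]]:
        return dict(self.planted_sets)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_shift": self.group_shift.to_dict(orient="index"),
            "covariate_slopes": self.covariate_slopes.to_dict(orient="index"),
            "planted_sets": {k: list(v) for k, v in self.planted_sets.items()},
            "censor_thresholds": self.censor_thresholds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# cohort

def _draw_covariate(rng: np.random.Generator, params: tuple, n: int) -> np.ndarray:
    kind = params[0]
    if kind == "normal":
        _, mean, sd = params
        return rng.normal(mean, sd, size=n)
    if kind == "poisson1":  # 1 + Poisson: stays >= 1 day
        _, lam = params
        return 1.0 + rng.poisson(lam, size=n).astype(float)
    if kind == "categorical":
        _, levels = params
        return rng.choice(np.asarray(levels), size=n)
    raise ValueError(f"unknown covariate distribution kind {kind!r}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate per-sample metadata: one row per subject x tissue.

    Covariates and traits are subject-level (constant across that subject's
    tissues); islet purity is present only for the islet tissue.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    subjects, groups = [], []
    i = 1
    for group, n in zip(GROUPS, spec.n_per_group):
        for _ in range(n):
            subjects.append(f"p{i:02d}")
            groups.append(group)
            i += 1
    n_subj = len(subjects)

    subj = pd.DataFrame({"subject": subjects, "group": groups})
    for cov, params in spec.covariate_params.items():
        subj[cov] = _draw_covariate(rng, params, n_subj)
    if "BMI" in subj:
        subj["BMI"] = subj["BMI"].clip(lower=16.0)
    if "CIT" in subj:
        subj["CIT"] = subj["CIT"].clip(lower=1.0)
    if "purity" in subj:
        subj["purity"] = subj["purity"].clip(5.0, 95.0)

    for trait, by_group in TRAIT_PARAMS.items():
        vals = np.empty(n_subj)
        for g, (mean, sd) in by_group.items():
            sel = subj["group"] == g
            vals[sel.to_numpy()] = rng.normal(mean, sd, size=int(sel.sum()))
        subj[trait] = np.clip(vals, 0.5, None)

    rows = []
    for tissue in spec.tissues:
        block = subj.copy()
        block.insert(0, "sample_id", block["subject"] + "_" + tissue)
        block.insert(2, "tissue", tissue)
        if "purity" in block and tissue != ISLET_TISSUE:
            block["purity"] = np.nan
        rows.append(block)
    meta = pd.concat(rows, ignore_index=True)
    return meta


# ---------------------------------------------------------------------------
# proteome

def generate_proteome(
    meta: pd.DataFrame,
    n_proteins: int,
    signal: SignalSpec,
    sets: GeneSetCollection,
    seed: int = 0,
) -> tuple[dict[str, IntensityMatrix], TruthRecord]:
    """Simulate complete per-tissue log2 matrices plus exact truth.

    Proteins are named after the collection's gene universe (so planted sets
    map onto matrix rows); if ``n_proteins`` exceeds the universe, filler
    genes outside every set are appended.
    """
    signal.validate(sets)
    universe = sorted(sets.all_genes())
    largest = max((len(m) for _, m in sets.items()), default=0)
    if n_proteins < largest:
        raise ValueError(
            f"n_proteins={n_proteins} smaller than the largest gene set ({largest})"
        )
    if n_proteins < len(universe):
        planted_genes = {
            g for name, _, _ in signal.planted_sets for g in sets[name]
        }
        keep = sorted(planted_genes)
        extra = [g for g in universe if g not in planted_genes]
        proteins = (keep + extra)[:n_proteins]
    else:
        filler = [f"X{i:05d}" for i in range(n_proteins - len(universe))]
        proteins = universe + filler
    proteins = sorted(proteins)

    rng = np.random.default_rng(seed)
    subjects = meta.drop_duplicates("subject").set_index("subject")
    subj_ids = subjects.index.to_list()
    n_subj = len(subj_ids)
    P = len(proteins)
    prot_index = pd.Index(proteins, name="protein_id")

    mu = rng.uniform(*signal.baseline_mu_range, size=P)
    subject_dev = rng.normal(0.0, signal.baseline_sd, size=(P, n_subj))

    group_shift = pd.DataFrame(0.0, index=prot_index, columns=list(GROUPS))
    planted: dict[str, tuple[float, str]] = {}
    for set_name, delta, group in signal.planted_sets:
        members = [g for g in sets[set_name] if g in group_shift.index]
        group_shift.loc[members, group] += delta
        planted[set_name] = (delta, group)

    cov_names = list(signal.covariate_effects)
    covariate_slopes = pd.DataFrame(0.0, index=prot_index, columns=cov_names)
    for cov, (slope, fraction) in signal.covariate_effects.items():
        n_affected = int(round(fraction * P))
        affected = rng.choice(P, size=n_affected, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_affected)
        covariate_slopes.iloc[affected, covariate_slopes.columns.get_loc(cov)] = (
            slope * signs
        )

    group_of = subjects["group"]
    shift_per_subject = group_shift.loc[:, group_of.to_numpy()].to_numpy()

    cov_term = np.zeros((P, n_subj))
    for cov in cov_names:
        if cov not in subjects.columns:
            raise ValueError(f"covariate {cov!r} not present in metadata")
        x = subjects[cov].to_numpy(dtype=float)
        x = np.where(np.isnan(x), np.nanmean(x), x)
        cov_term += np.outer(covariate_slopes[cov].to_numpy(), x - x.mean())

    base = mu[:, None] + subject_dev + shift_per_subject + cov_term

    matrices: dict[str, IntensityMatrix] = {}
    for tissue in meta["tissue"].unique():
        block = meta[meta["tissue"] == tissue]
        order = [subj_ids.index(s) for s in block["subject"]]
        eps = rng.normal(0.0, signal.residual_sd, size=(P, len(order)))
        values = base[:, order] + eps
        df = pd.DataFrame(values, index=prot_index, columns=block["sample_id"].to_list())
        matrices[tissue] = IntensityMatrix(df, tissue=tissue, scale="log2")

    truth = TruthRecord(
        group_shift=group_shift,
        covariate_slopes=covariate_slopes,
        planted_sets=planted,
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# missingness

def apply_missingness(
    m: IntensityMatrix,
    c: CensorSpec,
    seed: int = 0,
    truth: TruthRecord | None = None,
) -> IntensityMatrix:
    """Censor a complete matrix with probit-MNAR plus optional MCAR dropout.

    Per sample s: threshold T_s is the ``censor_quantile`` quantile of the
    sample's values; each cell goes missing with probability
    ``Phi(steepness * (T_s - v)) + mcar_rate`` (clipped to [0, 1]). Observed
    entries are unchanged. With ``censor_quantile = 0`` the threshold sits at
    the sample minimum, so only (at most) that single lowest value is at risk.
    """
    c.validate()
    if m.values.isna().any().any():
        raise ValueError("apply_missingness expects a complete matrix")
    rng = np.random.default_rng(seed)
    values = m.values.to_numpy(copy=True)
    thresholds: dict[str, float] = {}
    for j, sample in enumerate(m.sample_ids):
        col = values[:, j]
        t_s = float(np.quantile(col, c.censor_quantile))
        if c.censor_quantile == 0:
            # threshold below the support: no MNAR censoring
            p_mnar = np.zeros_like(col)
        elif np.isinf(c.censor_steepness):
            p_mnar = (col <= t_s).astype(float)
        else:
            p_mnar = stats.norm.cdf(c.censor_steepness * (t_s - col))
        p_miss = np.clip(p_mnar + c.mcar_rate, 0.0, 1.0)
        drop = rng.random(col.shape) < p_miss
        values[drop, j] = np.nan
        thresholds[str(sample)] = t_s
    out = IntensityMatrix(
        pd.DataFrame(values, index=m.values.index, columns=m.values.columns),
        tissue=m.tissue,
        scale=m.scale,
    )
    if truth is not None:
        truth.censor_thresholds[m.tissue] = thresholds
    return out


# ---------------------------------------------------------------------------
# gene sets and identifiers

def generate_gene_sets(
    n_sets: int,
    size_range: tuple[int, int] = (10, 40),
    universe_size: int = 1000,
    seed: int = 0,
    gmt_path: str | Path | None = None,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Random gene-set collection over a synthetic universe G00000..; each set
    samples its size uniformly from ``size_range`` and its members without
    replacement."""
    lo, hi = size_range
    if not (2 <= lo <= hi <= universe_size):
        raise ValueError(
            f"size_range {size_range} infeasible for universe of {universe_size}"
        )
    rng = np.random.default_rng(seed)
    universe = np.array([f"G{i:05d}" for i in range(universe_size)])
    collection = GeneSetCollection(name="synthetic")
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        collection.add(f"{prefix}{k:04d}", members.tolist(), "synthetic gene set")
    if gmt_path is not None:
        write_gmt(collection, gmt_path)
    return collection


def generate_identifier_lists(
    proteins: Sequence[str],
    ambiguity_rate: float,
    universe: Sequence[str],
    seed: int = 0,
) -> list[IdentifierRecord]:
    """Ordered candidate-identifier lists per protein, emulating DIA output
    where each quantified protein carries identifiers ranked by confidence.

    A fraction ``ambiguity_rate`` of records is made ambiguous: the true
    in-universe gene name is demoted to position >= 2 behind an accession-like
    decoy, or dropped entirely (half of the ambiguous records each).
    """
    if not 0 <= ambiguity_rate <= 1:
        raise ValueError("ambiguity_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe_set = set(universe)
    records: list[IdentifierRecord] = []
    for i, gene in enumerate(proteins):
        decoy = f"Q{rng.integers(10_000, 99_999)}"
        decoy2 = f"Q{rng.integers(10_000, 99_999)}"
        ambiguous = rng.random() < ambiguity_rate
        if not ambiguous:
            ordered = [gene, decoy]
        elif rng.random() < 0.5 and gene in universe_set:
            ordered = [decoy, gene, decoy2]
        else:
            ordered = [decoy, decoy2]
        records.append(IdentifierRecord(ordered_ids=tuple(ordered), true_gene=gene))
    return records
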