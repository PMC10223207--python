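"""Blomberg's K and its tip-shuffle permutation test.

K compares the observed ratio of trait variance measured two ways — the
ordinary mean squared error around the phylogenetically weighted (GLS)
mean, and the phylogenetically corrected MSE using the tree covariance
matrix V — with the value of that ratio expected under Brownian motion on
the same tree:

    a_hat = (1' V^-1 x) / (1' V^-1 1)
    MSE0  = (x - a_hat)'        (x - a_hat) / (n - 1)
    MSE   = (x - a_hat)' V^-1   (x - a_hat) / (n - 1)
    E     = [tr(V) - n / (1' V^-1 1)] / (n - 1)
    K     = (MSE0 / MSE) / E

K is about 1 for Brownian-motion traits, near 0 when trait variation is
independent of the phylogeny, and above 1 for traits more conserved than
Brownian motion predicts.

Significance is assessed nonparametrically: trait values are randomly
reassigned to the tips and the variance of the standardized independent
contrasts recomputed; phylogenetic structure makes the observed contrast
variance small, so the p-value counts permutations with a statistic less
than or equal to the observed one (add-one estimator, so p >= 1/(reps+1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .composition import SummaryStat, _summary
from .errors import NumericError, UndefinedSignalError, ValidationError
from .phylo import PhyloTree, VCVMatrix, contrast_operator, vcv_matrix

__all__ = [
    "TraitVector",
    "SignalResult",
    "blomberg_k",
    "phylosignal_test",
    "multi_phylosignal",
    "summarize_k",
    "read_trait_vector",
    "read_trait_table",
]

log = logging.getLogger(__name__)

#: relative jitter added to the diagonal when V cannot be factorized
JITTER_SCALE = 1e-10


@dataclass(frozen=True)
class TraitVector:
    """A named trait with one value per tree tip (no missing values)."""

    name: str
    values: dict[str, float]

    @classmethod
    def from_mapping(cls, name: str, values: Mapping[str, float]) -> "TraitVector":
        return cls(name, {str(k): float(v) for k, v in values.items()})

    def to_csv(self, path) -> None:
        pd.Series(self.values, name=self.name).rename_axis("tip_label").to_csv(path)


def read_trait_vector(path, name: str | None = None) -> TraitVector:
    """Read a two-column CSV (tip_label, value)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("trait CSV needs columns tip_label, value")
    tips = df.iloc[:, 0].astype(str)
    return TraitVector(
        name=name or str(df.columns[1]),
        values=dict(zip(tips, df.iloc[:, 1].astype(float))),
    )


def read_trait_table(path) -> list[TraitVector]:
    """Read a CSV with a tip-label first column and one trait per column."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return [
        TraitVector(name=str(col), values=df[col].astype(float).to_dict())
        for col in df.columns
    ]


@dataclass(frozen=True)
class SignalResult:
    """Outcome of one phylogenetic-signal test."""

    trait_name: str
    k: float
    p_value: float
    reps: int
    seed: int | None
    observed_stat: float


def _factorize(v: np.ndarray):
    """Cholesky factorization of V, retrying once with logged jitter."""
    try:
        return cho_factor(v, lower=True)
    except np.linalg.LinAlgError:
        jitter = JITTER_SCALE * np.trace(v) / v.shape[0]
        log.warning("VCV factorization failed; adding diagonal jitter %.3g", jitter)
        try:
            return cho_factor(v + jitter * np.eye(v.shape[0]), lower=True)
        except np.linalg.LinAlgError as exc:
            raise NumericError("VCV matrix singular after regularization") from exc


def blomberg_k(vcv: VCVMatrix, traits: Mapping[str, float] | TraitVector) -> float:
    """Blomberg's K of one trait given a tree covariance matrix."""
    values = traits.values if isinstance(traits, TraitVector) else traits
    x = vcv.align(values)
    n = x.size
    if n < 3:
        raise ValidationError("Blomberg's K needs at least three tips")
    v = vcv.matrix
    factor = _factorize(v)
    ones = np.ones(n)
    vinv_ones = cho_solve(factor, ones)
    denom = ones @ vinv_ones
    a_hat = (vinv_ones @ x) / denom
    r = x - a_hat
    mse0 = (r @ r) / (n - 1)
    if mse0 == 0.0:
        raise UndefinedSignalError("constant trait: K undefined")
    mse = (r @ cho_solve(factor, r)) / (n - 1)
    expected = (np.trace(v) - n / denom) / (n - 1)
    return float((mse0 / mse) / expected)


def _mse_stat_batch(vcv: VCVMatrix, xs: np.ndarray) -> np.ndarray:
    """Phylogenetically corrected MSE for each column of ``xs``."""
    n = xs.shape[0]
    factor = _factorize(vcv.matrix)
    ones = np.ones(n)
    vinv_ones = cho_solve(factor, ones)
    denom = ones @ vinv_ones
    a_hat = (vinv_ones @ xs) / denom
    r = xs - a_hat
    return np.einsum("ij,ij->j", r, cho_solve(factor, r)) / (n - 1)


def phylosignal_test(
    tree: PhyloTree,
    trait: TraitVector | Mapping[str, float],
    reps: int = 1000,
    seed: int | None = None,
    statistic: str = "pic_variance",
) -> SignalResult:
    """Permutation test of phylogenetic signal for one trait.

    The default statistic is the variance of the standardized independent
    contrasts; ``statistic="mse"`` uses the phylogenetically corrected MSE
    instead.  Both shrink when closely related tips have similar values, so
    p counts permutations with statistic <= observed, with the add-one
    convention p = (count + 1) / (reps + 1).
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if isinstance(trait, TraitVector):
        name, values = trait.name, trait.values
    else:
        name, values = "trait", dict(trait)

    vcv = vcv_matrix(tree)
    k = blomberg_k(vcv, values)

    rng = np.random.default_rng(seed)
    if statistic == "pic_variance":
        operator, labels = contrast_operator(tree)
        x = np.array([float(values[l]) for l in labels])
        observed = float(np.var(operator @ x, ddof=1))
        perms = rng.permuted(np.tile(x, (reps, 1)), axis=1)  # reps x n
        stats = np.var(operator @ perms.T, axis=0, ddof=1)
    elif statistic == "mse":
        x = vcv.align(values)
        observed = float(_mse_stat_batch(vcv, x[:, None])[0])
        perms = rng.permuted(np.tile(x, (reps, 1)), axis=1)
        stats = _mse_stat_batch(vcv, perms.T)
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")

    p = (int(np.sum(stats <= observed)) + 1) / (reps + 1)
    return SignalResult(
        trait_name=name, k=k, p_value=p, reps=reps, seed=seed, observed_stat=observed
    )


def multi_phylosignal(
    tree: PhyloTree,
    traits: Sequence[TraitVector],
    reps: int = 1000,
    seed: int | None = None,
    subset: Sequence[str] | None = None,
    statistic: str = "pic_variance",
) -> tuple[pd.DataFrame, SummaryStat | None]:
    """Signal test per trait plus a mean +/- SD summary of K over a subset.

    Each trait is tested with the same seed (identical traits therefore give
    identical results).  A failing trait is flagged in the ``error`` column
    and the others proceed.
    """
    rows = []
    k_by_name: dict[str, float] = {}
    for tv in traits:
        try:
            res = phylosignal_test(tree, tv, reps=reps, seed=seed, statistic=statistic)
            rows.append(
                {
                    "trait": tv.name,
                    "k": res.k,
                    "p_value": res.p_value,
                    "reps": res.reps,
                    "observed_stat": res.observed_stat,
                    "error": "",
                }
            )
            k_by_name[tv.name] = res.k
        except Exception as exc:  # propagate per-trait, continue others
            rows.append(
                {
                    "trait": tv.name,
                    "k": np.nan,
                    "p_value": np.nan,
                    "reps": reps,
                    "observed_stat": np.nan,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows).set_index("trait")
    summary = None
    if subset is not None:
        missing = [s for s in subset if s not in k_by_name]
        if missing:
            raise ValidationError(f"no K value for subset traits: {missing}")
        summary = summarize_k([k_by_name[s] for s in subset])
    return table, summary


def summarize_k(k_values: Sequence[float]) -> SummaryStat:
    """Mean +/- sample SD (n-1) of a collection of K values."""
    return _summary(np.asarray(k_values, dtype=float))
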