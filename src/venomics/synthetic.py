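"""Synthetic inputs with the statistical structure the analyses assume.

Each generator is a pure function of its parameters and a seed (NumPy's
PCG64 via ``default_rng``; the generator algorithm is pinned here so
fixtures stay stable across releases):

* Yule (pure-birth) trees — stand-in phylogenies with exponential waiting
  times between speciation events;
* Brownian-motion tip traits — multivariate normal with covariance
  sigma2 * V(tree) — and white-noise (i.i.d. normal) traits;
* Dirichlet compositional venom profiles (rows sum to 100%);
* two-level chromatogram/gel quantification records that invert the
  band-abundance formula exactly, for round-trip testing;
* binomial dose-mortality series with a probit dose-response on the
  log10-dose scale.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm

from .composition import AbundanceTable, Fraction, QuantInput
from .errors import InvalidInputError
from .phylo import PhyloTree, vcv_matrix
from .phylosignal import TraitVector
from .toxicology import DoseResponseSeries

__all__ = [
    "DEFAULT_DIRICHLET_ALPHA",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_white_noise_traits",
    "simulate_venom_profiles",
    "simulate_quant_input",
    "simulate_dose_response",
]

#: Dirichlet concentrations giving SVMP/PLA2/SVSP-dominated profiles with a
#: long tail of minor and trace families, qualitatively echoing real habu
#: venom tables (documentation of shape, not a claim of realism).
DEFAULT_DIRICHLET_ALPHA: dict[str, float] = {
    "SVMP": 3.3,
    "PLA2": 2.3,
    "SVSP": 1.6,
    "CTL": 0.9,
    "BPP/CNP": 0.7,
    "Disintegrin": 0.5,
    "CRISP": 0.35,
    "LAAO": 0.35,
    "VEGF": 0.2,
    "PDE": 0.1,
    "NGF": 0.06,
    "5NT": 0.06,
    "PLB": 0.05,
    "QC": 0.05,
}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed=None
) -> PhyloTree:
    """Pure-birth tree with ``n_tips`` tips, labelled t1..tn in birth order.

    Starting from two lineages at the root, the waiting time to the next
    split is Exponential(k * birth_rate) with k extant lineages; the last
    interval (n lineages) runs to the next unobserved event, so the expected
    depth is sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_tips < 3:
        raise InvalidInputError("need at least three tips")
    if birth_rate <= 0:
        raise InvalidInputError("birth rate must be positive")
    rng = _rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    first, second = dendropy.Node(), dendropy.Node()
    root.add_child(first)
    root.add_child(second)
    active = [first, second]
    birth_time = {first: 0.0, second: 0.0}
    now = 0.0
    while len(active) < n_tips:
        now += rng.exponential(1.0 / (len(active) * birth_rate))
        idx = int(rng.integers(len(active)))
        parent = active[idx]
        parent.edge.length = now - birth_time[parent]
        kids = [dendropy.Node(), dendropy.Node()]
        for k in kids:
            parent.add_child(k)
            birth_time[k] = now
        active[idx : idx + 1] = kids
    now += rng.exponential(1.0 / (len(active) * birth_rate))
    for i, leaf in enumerate(active, start=1):
        leaf.edge.length = now - birth_time[leaf]
        leaf.taxon = taxa.new_taxon(f"t{i}")
    return PhyloTree(tree)


def simulate_bm_traits(
    tree: PhyloTree, sigma2: float = 1.0, seed=None, name: str = "bm_trait"
) -> TraitVector:
    """Brownian-motion tip values: multivariate normal, covariance sigma2*V."""
    if sigma2 < 0:
        raise InvalidInputError("sigma2 must be nonnegative")
    rng = _rng(seed)
    vcv = vcv_matrix(tree)
    v = vcv.matrix + 1e-12 * np.eye(len(vcv.labels))
    chol = np.linalg.cholesky(v)
    x = np.sqrt(sigma2) * (chol @ rng.standard_normal(len(vcv.labels)))
    return TraitVector(name, dict(zip(vcv.labels, x.tolist())))


def simulate_white_noise_traits(
    tips: Sequence[str] | PhyloTree,
    sigma2: float = 1.0,
    seed=None,
    name: str = "wn_trait",
) -> TraitVector:
    """Phylogeny-free trait: i.i.d. Normal(0, sigma2) per tip."""
    if sigma2 < 0:
        raise InvalidInputError("sigma2 must be nonnegative")
    labels = list(tips.tip_labels) if isinstance(tips, PhyloTree) else list(tips)
    rng = _rng(seed)
    x = np.sqrt(sigma2) * rng.standard_normal(len(labels))
    return TraitVector(name, dict(zip(labels, x.tolist())))


def simulate_venom_profiles(
    n_taxa: int,
    dirichlet_alpha: Mapping[str, float] | None = None,
    seed=None,
) -> AbundanceTable:
    """Compositional profiles: each taxon's family percents are 100 times a
    Dirichlet draw, so every row sums to exactly 100."""
    alpha = dict(dirichlet_alpha or DEFAULT_DIRICHLET_ALPHA)
    if any(a <= 0 for a in alpha.values()):
        raise InvalidInputError("Dirichlet concentrations must be positive")
    rng = _rng(seed)
    draws = 100.0 * rng.dirichlet(list(alpha.values()), size=n_taxa)
    return AbundanceTable(
        pd.DataFrame(
            draws,
            index=[f"T{i + 1}" for i in range(n_taxa)],
            columns=list(alpha.keys()),
        )
    )


def simulate_quant_input(
    target_profile: Mapping[str, float],
    n_fractions: int = 6,
    seed=None,
) -> QuantInput:
    """Chromatogram/gel records whose quantification reproduces the target.

    Each family's percent mass is split into random positive parts; parts
    become gel bands grouped into fractions (some fractions are left whole).
    Peak areas and optical densities are randomly rescaled per fraction and
    lane, which the quantification must undo — the round trip through
    band_relative_abundance + aggregate_families recovers ``target_profile``
    to machine precision.
    """
    total = float(sum(target_profile.values()))
    if abs(total - 100.0) > 1e-6:
        raise InvalidInputError(f"target percents must sum to 100 (got {total})")
    if n_fractions < 1:
        raise InvalidInputError("need at least one fraction")
    rng = _rng(seed)

    parts: list[tuple[str, float]] = []
    for fam, pct in target_profile.items():
        if pct <= 0:
            continue
        k = int(rng.integers(1, 4))
        w = rng.dirichlet(np.ones(k))
        parts.extend((fam, pct * wi) for wi in w)
    # split the largest parts until there is at least one part per fraction
    while len(parts) < n_fractions:
        i = max(range(len(parts)), key=lambda j: parts[j][1])
        fam, m = parts.pop(i)
        parts.extend([(fam, m / 2), (fam, m / 2)])
    rng.shuffle(parts)

    n_whole = int(rng.integers(0, max(1, len(parts) - n_fractions) + 1))
    n_whole = min(n_whole, n_fractions - 1) if n_fractions > 1 else 0
    whole, rest = parts[:n_whole], parts[n_whole:]
    n_banded = n_fractions - n_whole
    # deal remaining parts round-robin so every banded fraction is non-empty
    lanes: list[list[tuple[str, float]]] = [[] for _ in range(n_banded)]
    for i, part in enumerate(rest):
        lanes[i % n_banded].append(part)

    area_scale = float(rng.uniform(0.5, 5.0))
    fractions: list[Fraction] = []
    fid = 0
    for fam, mass in whole:
        fid += 1
        fractions.append(Fraction(f"F{fid}", mass * area_scale, (), (fam,)))
    for lane in lanes:
        fid += 1
        lane_mass = sum(m for _, m in lane)
        density_scale = float(rng.uniform(0.5, 5.0))
        fractions.append(
            Fraction(
                f"F{fid}",
                lane_mass * area_scale,
                tuple(m * density_scale for _, m in lane),
                tuple(fam for fam, _ in lane),
            )
        )
    return QuantInput(tuple(fractions))


def simulate_dose_response(
    true_ld50: float,
    log_slope: float = 2.0,
    doses: Sequence[float] = (),
    n: int = 4,
    seed=None,
) -> DoseResponseSeries:
    """Binomial mortality with a probit dose-response:
    P(death | dose d) = Phi(log_slope * (log10 d - log10 LD50))."""
    if true_ld50 <= 0 or log_slope <= 0:
        raise InvalidInputError("true_ld50 and log_slope must be positive")
    doses = tuple(float(d) for d in doses)
    if any(d <= 0 for d in doses):
        raise InvalidInputError("doses must be positive")
    rng = _rng(seed)
    p = norm.cdf(log_slope * (np.log10(doses) - np.log10(true_ld50)))
    deaths = rng.binomial(n, p)
    return DoseResponseSeries(doses, tuple([n] * len(doses)), tuple(int(k) for k in deaths))
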