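"""Synthetic inputs: Yule trees, Brownian traits under Pagel transforms,
climate-like covariates, and the packaged Drosophilidae genome-size table.

The generators mimic the statistical structure of a genome-size study on a
drosophilid phylogeny: trait location around 215 Mbp with roughly a 3-fold
spread across tips, ultrametric pure-birth trees, and covariates that carry
their own phylogenetic signal.  Everything is bit-reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np
import pandas as pd

from .phylo import Phylogeny, PhyloCovariance, TransformParams, transform_delta, transform_lambda

__all__ = [
    "SimulationSpec",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_climate",
    "table1_fixture",
    "transformed_vcv",
    "CLIMATE_VARIABLES",
]

#: default BM rate: on a unit-rate Yule tree of ~90 tips (depth ~ 4) this
#: yields a tip standard deviation of ~60 Mbp, i.e. roughly the 3-fold
#: (139.9-395.2 Mbp) spread of the packaged genome-size table
DEFAULT_SIGMA2 = 1000.0
DEFAULT_ROOT = 215.0


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic trait simulation."""

    n_tips: int = 87
    birth_rate: float = 1.0
    trait_root: float = DEFAULT_ROOT
    trait_sigma2: float = DEFAULT_SIGMA2
    transform: TransformParams = field(default_factory=TransformParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.trait_sigma2 < 0:
            raise ValueError("trait_sigma2 must be >= 0")


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips.

    Starting from the two crown lineages, waiting times between speciation
    events are exponential with rate (number of lineages) * birth_rate and
    the splitting lineage is chosen uniformly; after the last event all
    open branches are extended by a final waiting time, so the tree is
    ultrametric.  Tips are labeled t1..tN in order of appearance.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    t = 0.0
    # active lineages: (node, birth time of its pending edge)
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = root.new_child()
        active.append((child, 0.0))
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node, born = active.pop(rng.integers(k))
        node.edge.length = t - born
        for _ in range(2):
            child = node.new_child()
            active.append((child, t))
    t += rng.exponential(1.0 / (len(active) * birth_rate))
    for i, (node, born) in enumerate(active, start=1):
        node.edge.length = t - born
        node.taxon = taxa.new_taxon(label=f"t{i}")
    return Phylogeny(tree)


def transformed_vcv(tree: Phylogeny, transform: TransformParams) -> PhyloCovariance:
    """Tree covariance under kappa, then delta, then lambda (in that order:
    branch lengths, node depths, off-diagonal scaling)."""
    C = tree.vcv(kappa=None if transform.kappa == 1.0 else transform.kappa)
    if transform.delta != 1.0:
        C = transform_delta(C, transform.delta)
    if transform.lambda_ != 1.0:
        C = transform_lambda(C, transform.lambda_)
    return C


def simulate_bm_traits(tree: Phylogeny, spec: SimulationSpec) -> pd.Series:
    """Draw tip traits from N(root * 1, sigma2 * transformed VCV).

    Sampling uses the (ridged, if necessary) Cholesky factor of the
    transformed covariance, so draws are exact and reproducible under the
    spec's seed.
    """
    C = transformed_vcv(tree, spec.transform)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(C.n)
    if spec.trait_sigma2 == 0:
        vals = np.full(C.n, spec.trait_root)
    else:
        L = C.cholesky()
        vals = spec.trait_root + np.sqrt(spec.trait_sigma2) * (L @ z)
    return pd.Series(vals, index=list(C.labels), name="value")


#: the eight climate covariates of the adaptive-hypothesis test, with a
#: plausible (location, scale) for each on its natural measurement scale
CLIMATE_VARIABLES: dict[str, tuple[float, float]] = {
    "critical_thermal_maximum": (38.0, 1.5),  # degrees C
    "minimum_temperature": (6.0, 5.0),
    "maximum_temperature": (30.0, 4.0),
    "annual_mean_temperature": (18.0, 5.0),
    "annual_precipitation": (1200.0, 400.0),  # mm
    "precipitation_wettest_month": (200.0, 80.0),
    "precipitation_driest_month": (40.0, 25.0),
    "latitude": (0.0, 20.0),  # degrees
}


def simulate_climate(
    tree: Phylogeny,
    n_vars: int = 8,
    signal_lambda: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Phylogenetically autocorrelated climate-like covariates.

    Each variable is an independent BM trait evolved on the tree with the
    given Pagel's lambda, standardized and rescaled to a plausible range
    for that variable.  With ``signal_lambda = 1`` the covariates carry
    full phylogenetic signal — the scenario in which ordinary regression of
    one phylogenetic trait on another produces spurious associations that
    PGLS removes; with ``signal_lambda = 0`` they are tree-independent.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    names = list(CLIMATE_VARIABLES)
    scales = dict(CLIMATE_VARIABLES)
    for i in range(len(names), n_vars):
        names.append(f"covariate_{i + 1}")
        scales[names[-1]] = (0.0, 1.0)
    names = names[:n_vars]

    transform = TransformParams(lambda_=signal_lambda)
    C = transformed_vcv(tree, transform)
    L = C.cholesky()
    rng = np.random.default_rng(seed)
    cols = {}
    for name in names:
        loc, scale = scales[name]
        raw = L @ rng.standard_normal(C.n)
        z = (raw - raw.mean()) / (raw.std() if raw.std() > 0 else 1.0)
        cols[name] = loc + scale * z
    return pd.DataFrame(cols, index=list(C.labels))


#: sha256 over the sorted "species=value" pairs of the packaged table;
#: guards the fixture against accidental edits
_TABLE1_SHA256 = "2d945352b3e36d1e65439d2c273555540b437d8ea6a8918e789611829c66cc5f"


def table1_fixture() -> pd.Series:
    """The packaged 87-species Drosophilidae female 1C genome-size table
    (Mbp), transcribed to one decimal as published; species names use genus
    initials and underscores (e.g. ``D_busckii``)."""
    ref = resources.files("phylotempo.data").joinpath("table1_genome_sizes.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh)
    return pd.Series(df["value"].to_numpy(), index=df["species"].tolist(), name="value")
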