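"""Feature encoders: network adjacency, neighborhood term enrichment, PseAAC.

Each protein is represented by up to three feature groups:

* **network** — one feature per network node, valued by the confidence
  of the direct interaction between the query protein and that node
  (0 when no interaction exists);
* **kegg / go** — one feature per annotation term, valued by the
  -log10 upper-tail hypergeometric p-value measuring over-representation
  of the term's proteins within the query's network neighborhood
  (the "enrichment score");
* **pseaac** — pseudo-amino-acid composition of the sequence: the
  20 residue frequencies plus lambda sequence-order correlation factors
  per physicochemical property.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import STANDARD_RESIDUES, TermCatalog, WeightedNetwork

logger = logging.getLogger(__name__)

RESIDUES = sorted(STANDARD_RESIDUES)  # alphabetical, fixes AAC feature order

# Atchley's five multivariate factor scores per residue (columns: factor
# I polarity, II secondary structure, III molecular volume, IV codon
# diversity, V electrostatic charge). Values are re-standardized over the
# 20 residues before use, so only relative spacing matters.
_ATCHLEY = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-0.274, -0.474, -0.726, 1.471, -0.431),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

# declared block order of the five properties (fixed; defines feature order)
PROPERTY_NAMES = (
    "codon_diversity",       # Atchley factor IV
    "electrostatic_charge",  # Atchley factor V
    "molecular_volume",      # Atchley factor III
    "polarity",              # Atchley factor I
    "secondary_structure",   # Atchley factor II
)
_FACTOR_COLUMN = {
    "codon_diversity": 3,
    "electrostatic_charge": 4,
    "molecular_volume": 2,
    "polarity": 0,
    "secondary_structure": 1,
}


def _default_property_tables() -> dict[str, dict[str, float]]:
    return {
        name: {aa: _ATCHLEY[aa][_FACTOR_COLUMN[name]] for aa in RESIDUES}
        for name in PROPERTY_NAMES
    }


@dataclass
class FeatureMatrix:
    """Dense samples x features matrix with named features and group tags."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN or infinite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    def to_csv(self, path, groups_path=None) -> None:
        """CSV with an id column; optional sidecar JSON for the group tags."""
        frame = self.to_frame()
        frame.index.name = "protein_id"
        frame.to_csv(path)
        if groups_path is not None:
            with open(groups_path, "w") as fh:
                json.dump(self.groups, fh, indent=0, sort_keys=True)

    @classmethod
    def from_csv(cls, path, groups_path=None) -> "FeatureMatrix":
        frame = pd.read_csv(path, index_col=0)
        groups: dict[str, str] = {}
        if groups_path is not None:
            with open(groups_path) as fh:
                groups = json.load(fh)
        return cls(
            sample_ids=[str(i) for i in frame.index],
            feature_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            groups=groups,
        )


@dataclass
class NeighborhoodSet:
    """A query protein together with its network neighbors (the set PS)."""

    query: str
    members: set[str]


@dataclass
class EnrichmentConfig:
    universe: set[str] | None = None  # None -> network nodes ∩ catalog members
    min_confidence: float = 0.0
    p_floor: float = 1e-300

    def __post_init__(self) -> None:
        if not 0.0 < self.p_floor < 1.0:
            raise ValueError("p_floor must be in (0, 1)")
        if not 0.0 <= self.min_confidence < 1.0:
            raise ValueError("min_confidence must be in [0, 1)")


@dataclass
class PseAACConfig:
    lam: int = 50
    weight: float = 0.15
    properties: dict[str, dict[str, float]] = field(default_factory=_default_property_tables)
    include_aac: bool = True

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lam must be >= 1")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        for name, table in self.properties.items():
            missing = STANDARD_RESIDUES - set(table)
            if missing:
                raise ValueError(f"property {name!r} missing residues {sorted(missing)}")


def encode_network(query_ids: list[str], network: WeightedNetwork) -> FeatureMatrix:
    """Weighted adjacency rows: one feature per network node.

    The value of feature ``net:v`` for query ``q`` is the confidence of
    the interaction (q, v), or 0 when no interaction exists or the query
    is not a network node.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot encode against an empty network")
    nodes = network.nodes
    col = {v: j for j, v in enumerate(nodes)}
    values = np.zeros((len(query_ids), len(nodes)))
    for i, q in enumerate(query_ids):
        for v, w in network.neighbors(q).items():
            values[i, col[v]] = w
    names = [f"net:{v}" for v in nodes]
    return FeatureMatrix(
        sample_ids=list(query_ids),
        feature_names=names,
        values=values,
        groups={n: "network" for n in names},
    )


def neighborhood(
    query: str, network: WeightedNetwork, min_confidence: float = 0.0
) -> NeighborhoodSet:
    """PS = {query} ∪ {v : score(query, v) > min_confidence}."""
    members = {query}
    for v, w in network.neighbors(query).items():
        if w > min_confidence:
            members.add(v)
    return NeighborhoodSet(query=query, members=members)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of marked items, n the draw
    size, k the observed number of marked items in the draw.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent arguments K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def default_universe(network: WeightedNetwork, catalog: TermCatalog) -> set[str]:
    """Background population: network nodes that carry any annotation."""
    return set(network.nodes) & catalog.all_members()


def encode_enrichment(
    query_ids: list[str],
    network: WeightedNetwork,
    catalog: TermCatalog,
    config: EnrichmentConfig | None = None,
) -> FeatureMatrix:
    """Neighborhood enrichment scores: one feature per catalog term.

    For each query, the neighborhood set PS (query + interacting
    partners above ``min_confidence``) is tested for over-representation
    of each term's member set against the background universe; the score
    is -log10 of the upper-tail hypergeometric p-value, capped at
    -log10(p_floor). Terms with no member inside the universe score 0
    for every query (logged once per term).
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    config = config or EnrichmentConfig()
    universe = config.universe
    if universe is None:
        universe = default_universe(network, catalog)
    N = len(universe)
    group = {"pathway": "kegg", "go": "go"}.get(catalog.kind, "other")
    cap = -math.log10(config.p_floor)

    term_sets = {}
    for term in catalog.terms:
        tset = catalog.membership[term] & universe
        if not tset:
            logger.warning("term %s has no members in the universe; scoring 0", term)
        term_sets[term] = tset

    values = np.zeros((len(query_ids), len(catalog)))
    for i, q in enumerate(query_ids):
        ps = neighborhood(q, network, config.min_confidence).members & universe
        n = len(ps)
        for j, term in enumerate(catalog.terms):
            tset = term_sets[term]
            if not tset or n == 0:
                continue
            k = len(ps & tset)
            p = max(hypergeom_tail(k, len(tset), n, N), config.p_floor)
            values[i, j] = min(-math.log10(p), cap)
    names = list(catalog.terms)
    return FeatureMatrix(
        sample_ids=list(query_ids),
        feature_names=names,
        values=values,
        groups={t: group for t in names},
    )


def _standardize_table(table: dict[str, float]) -> dict[str, float]:
    vals = np.array([table[aa] for aa in RESIDUES])
    mu, sd = vals.mean(), vals.std()  # population std over the 20 residues
    if sd == 0:
        raise ValueError("property table is constant over the 20 residues")
    return {aa: (table[aa] - mu) / sd for aa in RESIDUES}


def encode_pseaac(sequence: str, config: PseAACConfig | None = None) -> np.ndarray:
    """Pseudo-amino-acid composition of one sequence.

    Layout: 20 amino-acid composition components (summing to 1) followed
    by one block of ``lam`` sequence-order components per property, in
    the declared property order — 20 + 5*50 = 270 at defaults. The j-th
    order factor of property p is the mean squared difference of the
    standardized property profile at sequence lag j; block components
    are w*theta_j / (1 + w*sum_j theta_j).
    """
    config = config or PseAACConfig()
    seq = sequence.upper()
    bad = set(seq) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"sequence contains non-standard residues {sorted(bad)}")
    L = len(seq)
    if L <= config.lam:
        raise ValueError(
            f"sequence length {L} must exceed lambda={config.lam} "
            f"(minimum {config.lam + 1} residues)"
        )
    parts: list[np.ndarray] = []
    if config.include_aac:
        counts = np.array([seq.count(aa) for aa in RESIDUES], dtype=float)
        parts.append(counts / L)
    for name in config.properties:  # insertion order = declared block order
        table = _standardize_table(config.properties[name])
        profile = np.array([table[aa] for aa in seq])
        theta = np.empty(config.lam)
        for j in range(1, config.lam + 1):
            diff = profile[j:] - profile[:-j]
            theta[j - 1] = np.mean(diff * diff)
        denom = 1.0 + config.weight * theta.sum()
        parts.append(config.weight * theta / denom)
    return np.concatenate(parts)


def pseaac_feature_names(config: PseAACConfig | None = None) -> list[str]:
    config = config or PseAACConfig()
    names = []
    if config.include_aac:
        names += [f"aac:{aa}" for aa in RESIDUES]
    for prop in config.properties:
        names += [f"pse:{prop}:{j}" for j in range(1, config.lam + 1)]
    return names


def encode_pseaac_matrix(
    records, config: PseAACConfig | None = None
) -> FeatureMatrix:
    """PseAAC-encode a list of protein records into a FeatureMatrix."""
    config = config or PseAACConfig()
    names = pseaac_feature_names(config)
    rows = [encode_pseaac(r.sequence, config) for r in records]
    return FeatureMatrix(
        sample_ids=[r.id for r in records],
        feature_names=names,
        values=np.vstack(rows) if rows else np.zeros((0, len(names))),
        groups={n: "pseaac" for n in names},
    )


def concat_features(*matrices: FeatureMatrix) -> FeatureMatrix:
    """Horizontal concatenation; requires identical sample-id order."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    first = matrices[0]
    names: list[str] = []
    groups: dict[str, str] = {}
    blocks = []
    for m in matrices:
        if m.sample_ids != first.sample_ids:
            raise ValueError("sample id order mismatch between feature matrices")
        for n in m.feature_names:
            if n in groups:
                raise ValueError(f"feature name collision: {n!r}")
            groups[n] = m.groups.get(n, "other")
        names.extend(m.feature_names)
        blocks.append(m.values)
    return FeatureMatrix(
        sample_ids=list(first.sample_ids),
        feature_names=names,
        values=np.hstack(blocks),
        groups=groups,
    )
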