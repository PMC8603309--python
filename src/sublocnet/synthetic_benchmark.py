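"""Seeded synthetic benchmarks with the structure the pipeline assumes.

The generator emulates, at reduced scale, the statistical shape of a
curated localization dataset: strongly imbalanced location classes
(geometric size decay, default 60 down to 6 across 6 classes), a
confidence-weighted interaction network whose *within-class*
connectivity carries the class signal, annotation terms enriched in
class members, and sequences with class-biased residue composition.

Each class owns a small set of hub proteins. Members attach to their
own hubs with probability ``p_in`` at high confidence and to foreign
hubs with probability ``p_out`` at low confidence. Annotation terms for
a class contain the class hubs, plus those members that are actually
attached to the class module (so the annotation signal flows through
the network: setting p_in = p_out removes *all* class signal, which is
what the null-control experiments rely on). Noise terms sample members
uniformly. The ``truth`` registry names the planted informative
features — the hub adjacency columns and the class terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoders import EnrichmentConfig, RESIDUES
from .io_formats import (
    LabeledDataset,
    ProteinRecord,
    TermCatalog,
    WeightedNetwork,
    write_fasta,
    write_gmt,
    write_labels,
    write_network,
)


@dataclass
class BenchmarkConfig:
    n_classes: int = 6
    class_sizes: list[int] | None = None  # None -> geometric n_max..n_min
    n_max: int = 60
    n_min: int = 6
    hubs_per_class: int = 5
    background_nodes: int = 100
    p_in: float = 0.3
    p_out: float = 0.02
    conf_in: tuple[float, float] = (0.7, 0.99)
    conf_out: tuple[float, float] = (0.15, 0.5)
    terms_per_class: int = 10
    noise_terms: int = 50
    term_hit_prob: float = 0.6
    term_noise_prob: float = 0.05
    seq_len_range: tuple[int, int] = (100, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.p_in < self.p_out:
            raise ValueError("p_in must be >= p_out")
        for lo, hi in (self.conf_in, self.conf_out):
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError("confidence ranges must lie in (0, 1]")
        if self.class_sizes is not None:
            if len(self.class_sizes) != self.n_classes:
                raise ValueError("class_sizes length must equal n_classes")
            if any(s < 1 for s in self.class_sizes):
                raise ValueError("class sizes must be >= 1")
        elif not 1 <= self.n_min <= self.n_max:
            raise ValueError("need 1 <= n_min <= n_max")
        if self.hubs_per_class < 1 or self.terms_per_class < 1:
            raise ValueError("hubs_per_class and terms_per_class must be >= 1")

    def resolved_class_sizes(self) -> list[int]:
        if self.class_sizes is not None:
            return list(self.class_sizes)
        k = self.n_classes
        if k == 1:
            return [self.n_max]
        ratio = (self.n_min / self.n_max) ** (1.0 / (k - 1))
        return [max(1, round(self.n_max * ratio**i)) for i in range(k)]


@dataclass
class Benchmark:
    dataset: LabeledDataset
    network: WeightedNetwork
    catalogs: dict[str, TermCatalog]  # keys: "kegg", "go"
    truth: dict
    config: BenchmarkConfig

    def enrichment_universe(self) -> set[str]:
        """Shared background for both catalogs: every network node."""
        return set(self.network.nodes)

    def enrichment_config(self) -> EnrichmentConfig:
        return EnrichmentConfig(universe=self.enrichment_universe())

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": outdir / "network.tsv",
            "kegg": outdir / "kegg.gmt",
            "go": outdir / "go.gmt",
            "fasta": outdir / "sequences.fasta",
            "labels": outdir / "labels.tsv",
            "truth": outdir / "truth.json",
        }
        write_network(self.network, paths["network"], score_scale="thousandths")
        write_gmt(self.catalogs["kegg"], paths["kegg"])
        write_gmt(self.catalogs["go"], paths["go"])
        write_fasta(self.dataset.records, paths["fasta"])
        write_labels(
            {r.id: r.label for r in self.dataset.records}, paths["labels"]
        )
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


def generate_benchmark(config: BenchmarkConfig | None = None) -> Benchmark:
    """Build a fully seeded benchmark (same seed => identical files)."""
    config = config or BenchmarkConfig()
    sizes = config.resolved_class_sizes()
    root = np.random.SeedSequence(config.seed)
    rng_net, rng_term, rng_seq = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    classes = [f"C{i + 1}" for i in range(config.n_classes)]
    members: dict[str, list[str]] = {}
    pid = 0
    for c, size in zip(classes, sizes):
        members[c] = []
        for _ in range(size):
            pid += 1
            members[c].append(f"P{pid:04d}")
    hubs = {
        c: [f"HUB_{c}_{j + 1}" for j in range(config.hubs_per_class)] for c in classes
    }
    background = [f"BG{j + 1:03d}" for j in range(config.background_nodes)]

    all_members = [p for c in classes for p in members[c]]
    all_hubs = [h for c in classes for h in hubs[c]]
    node_order = all_members + all_hubs + background

    # --- network ---------------------------------------------------------
    net = WeightedNetwork(nodes=node_order)
    attached: dict[str, set[str]] = {c: set() for c in classes}

    def draw_conf(rng, rng_range) -> float:
        lo, hi = rng_range
        return float(rng.uniform(lo, hi))

    for c in classes:
        for p in members[c]:
            for c2 in classes:
                for h in hubs[c2]:
                    if c2 == c:
                        if rng_net.random() < config.p_in:
                            net.add_edge(p, h, draw_conf(rng_net, config.conf_in))
                            attached[c].add(p)
                    elif rng_net.random() < config.p_out:
                        net.add_edge(p, h, draw_conf(rng_net, config.conf_out))
    for b in background:
        for h in all_hubs:
            if rng_net.random() < config.p_out:
                net.add_edge(b, h, draw_conf(rng_net, config.conf_out))

    # --- term catalogs ---------------------------------------------------
    catalogs = {"kegg": TermCatalog(kind="pathway"), "go": TermCatalog(kind="go")}
    class_terms: dict[str, list[str]] = {c: [] for c in classes}
    for c in classes:
        for t in range(config.terms_per_class):
            kind = "kegg" if t % 2 == 0 else "go"
            term = f"{kind.upper()}_{c}_T{t + 1}"
            term_members = set(hubs[c])
            for p in members[c]:
                # annotation propagates through the class module: only
                # network-attached members can carry the class terms
                if p in attached[c] and rng_term.random() < config.term_hit_prob:
                    term_members.add(p)
            catalogs[kind].add(term, term_members)
            class_terms[c].append(term)
    population = all_members + all_hubs + background
    for t in range(config.noise_terms):
        kind = "kegg" if t % 2 == 0 else "go"
        term = f"{kind.upper()}_NOISE_T{t + 1}"
        term_members = {
            p for p in population if rng_term.random() < config.term_noise_prob
        }
        if not term_members:
            term_members = {population[int(rng_term.integers(len(population)))]}
        catalogs[kind].add(term, term_members)

    # --- sequences -------------------------------------------------------
    records: list[ProteinRecord] = []
    lo_len, hi_len = config.seq_len_range
    for c in classes:
        # class-biased residue usage: uniform blended with a Dirichlet(1) draw
        probs = 0.5 / 20.0 + 0.5 * rng_seq.dirichlet(np.ones(20))
        for p in members[c]:
            length = int(rng_seq.integers(lo_len, hi_len + 1))
            seq = "".join(rng_seq.choice(RESIDUES, size=length, p=probs))
            records.append(ProteinRecord(id=p, sequence=seq, label=c))

    dataset = LabeledDataset(records=records, classes=list(classes))
    truth = {
        "classes": classes,
        "class_sizes": dict(zip(classes, sizes)),
        "hubs": {c: hubs[c] for c in classes},
        "network_features": {c: [f"net:{h}" for h in hubs[c]] for c in classes},
        "terms": class_terms,
        "planted_features": sorted(
            [f"net:{h}" for h in all_hubs]
            + [t for ts in class_terms.values() for t in ts]
        ),
        "attached_members": {c: sorted(attached[c]) for c in classes},
    }
    return Benchmark(
        dataset=dataset, network=net, catalogs=catalogs, truth=truth, config=config
    )


@dataclass
class WorkedExample:
    """Tiny 10-protein fixture with a hand-checkable enrichment score.

    The query p1 interacts with p2..p5, so its neighborhood set PS has 5
    proteins; the term T1 has 4 members of which 3 fall inside PS.
    Against the 10-protein universe the upper-tail hypergeometric
    p-value is 66/252 and the enrichment score -log10(66/252) ~ 0.5819.
    """

    network: WeightedNetwork
    catalog: TermCatalog
    query: str = "p1"
    term: str = "T1"

    @property
    def expected_score(self) -> float:
        return -math.log10(66.0 / 252.0)

    def enrichment_config(self) -> EnrichmentConfig:
        return EnrichmentConfig(universe=set(self.network.nodes))

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"network": outdir / "network.tsv", "gmt": outdir / "terms.gmt"}
        write_network(self.network, paths["network"])
        write_gmt(self.catalog, paths["gmt"])
        return paths


def generate_worked_example(disjoint_term: bool = False) -> WorkedExample:
    """10-protein universe; overlap(PS, T1) = 3 of K=4, n=5, N=10.

    With ``disjoint_term`` the term avoids PS entirely, so the score is 0.
    """
    proteins = [f"p{i}" for i in range(1, 11)]
    edges = [("p1", p, 0.9) for p in ("p2", "p3", "p4", "p5")]
    # keep the remaining proteins connected (and thus serializable) without
    # touching p1's neighborhood
    edges += [("p6", "p7", 0.2), ("p7", "p8", 0.2), ("p8", "p9", 0.2), ("p9", "p10", 0.2)]
    net = WeightedNetwork(nodes=proteins, edges=edges)
    catalog = TermCatalog(kind="go")
    if disjoint_term:
        catalog.add("T1", {"p6", "p7", "p8", "p9"})
    else:
        catalog.add("T1", {"p2", "p3", "p4", "p6"})
    return WorkedExample(network=net, catalog=catalog)
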