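"""Community structure, participation, and the hub taxonomy of a connectome.

Communities are found with the weighted Louvain algorithm run many times
(default 100) from distinct RNG substreams, combined by consensus
clustering: a node-pair agreement matrix over the iterations is
thresholded at 0.5 and re-clustered with Louvain until the partition is
stable.  The modularity Q of the consensus partition is recomputed on the
original network.  Q near 1 indicates strong community structure; Q in
0-0.3 is the range typical of random networks.

Hubs are nodes of the group-averaged network whose degree or strength is
at least one standard deviation above the network mean (the two bases
are evaluated independently; a node may be a hub on both).  Each hub is
classified by its participation index PI = 1 - sum_m (kappa_im / k_i)^2,
the spread of its edges over modules: provincial (PI <= 0.3, edges
mostly within its own module), connector (0.3 < PI <= 0.75), otherwise
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .build import WeightedNetwork

__all__ = [
    "Partition",
    "HubRecord",
    "HubComparison",
    "louvain_partition",
    "modularity_q",
    "participation_coefficient",
    "identify_hubs",
    "classify_hub",
    "match_modules",
    "module_migration",
    "compare_hubs",
]


@dataclass(frozen=True)
class Partition:
    """Node-to-community assignment with its modularity score."""

    assignment: np.ndarray  # community id per node, 0-based
    q: float
    iteration_qs: tuple[float, ...]
    method: str
    labels: tuple[str, ...] = ()

    @property
    def n_modules(self) -> int:
        return int(len(np.unique(self.assignment)))

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module)


@dataclass(frozen=True)
class HubRecord:
    node: str
    basis: str  # "degree" | "strength"
    value: float
    module: int
    participation: float
    klass: str  # "provincial" | "connector" | "unclassified"


@dataclass(frozen=True)
class HubComparison:
    """Hub and module bookkeeping between two group-level networks."""

    shared: frozenset
    gained: frozenset
    lost: frozenset
    status_changes: tuple
    module_migrations: tuple = ()
    module_size_changes: dict = field(default_factory=dict)


def _graph(net: WeightedNetwork) -> nx.Graph:
    G = nx.from_numpy_array(net.weights)
    return G


def modularity_q(net: WeightedNetwork, assignment: np.ndarray) -> float:
    """Weighted Newman-Girvan modularity of the given node assignment.

    ``Q = (1/2W) sum_ij (w_ij - s_i s_j / 2W) delta(c_i, c_j)`` with W the
    total undirected edge weight and s the nodal strengths.
    """
    assignment = np.asarray(assignment)
    if assignment.shape[0] != net.n_nodes:
        raise ValueError("assignment must cover every node")
    w = net.weights
    two_w = w.sum()
    if two_w == 0:
        raise ValueError("modularity undefined on an edgeless network")
    strength = w.sum(axis=1)
    q = 0.0
    for c in np.unique(assignment):
        idx = assignment == c
        q += w[np.ix_(idx, idx)].sum() / two_w - (strength[idx].sum() / two_w) ** 2
    return float(q)


def _sets_to_assignment(communities, n: int) -> np.ndarray:
    assignment = np.empty(n, dtype=int)
    for cid, nodes in enumerate(communities):
        assignment[list(nodes)] = cid
    return assignment


def _canonical(assignment: np.ndarray) -> np.ndarray:
    """Relabel communities by descending size (ties by smallest member node)."""
    ids, counts = np.unique(assignment, return_counts=True)
    first = np.array([np.flatnonzero(assignment == c)[0] for c in ids])
    order = np.lexsort((first, -counts))
    remap = {int(ids[o]): rank for rank, o in enumerate(order)}
    return np.array([remap[int(c)] for c in assignment])


def louvain_partition(
    net: WeightedNetwork,
    n_iterations: int = 100,
    seed: int = 0,
    resolution: float = 1.0,
    max_consensus_rounds: int = 20,
) -> Partition:
    """Multi-iteration Louvain with consensus clustering.

    Runs weighted Louvain ``n_iterations`` times with distinct seeded
    substreams, builds the node-pair agreement matrix, thresholds it at
    0.5, and re-clusters the agreement graph with Louvain until two
    successive rounds agree.  Returns the consensus partition with Q
    recomputed on the original network, plus all per-iteration Q values.
    """
    if not np.any(net.weights > 0):
        raise ValueError("Louvain requires at least one edge")
    n = net.n_nodes
    n_reruns = 10  # reruns per consensus round on the agreement graph
    G = _graph(net)
    ss = np.random.SeedSequence(seed)
    substreams = iter(ss.spawn(n_iterations + max_consensus_rounds * n_reruns))

    def run_louvain(graph):
        s = int(next(substreams).generate_state(1)[0] % (2**31))
        comms = nx.community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=s
        )
        return _sets_to_assignment(comms, n)

    assignments = np.empty((n_iterations, n), dtype=int)
    iteration_qs = []
    for it in range(n_iterations):
        assignments[it] = run_louvain(G)
        iteration_qs.append(modularity_q(net, assignments[it]))

    def agreement(partitions: np.ndarray) -> np.ndarray:
        agree = np.zeros((n, n))
        for a in partitions:
            agree += a[:, None] == a[None, :]
        agree /= len(partitions)
        agree[agree < 0.5] = 0.0
        np.fill_diagonal(agree, 0.0)
        return agree

    current = assignments
    consensus = assignments[int(np.argmax(iteration_qs))]
    for _ in range(max_consensus_rounds):
        agree = agreement(current)
        if not np.any(agree > 0):
            # no pair co-assigned above chance: fall back to the max-Q run
            break
        agraph = nx.from_numpy_array(agree)
        # canonical relabeling so equivalent partitions compare equal
        reruns = np.stack([_canonical(run_louvain(agraph)) for _ in range(n_reruns)])
        consensus = reruns[0]
        if all((r == consensus).all() for r in reruns[1:]):
            break
        current = reruns
    consensus = _canonical(consensus)
    return Partition(
        assignment=consensus,
        q=modularity_q(net, consensus),
        iteration_qs=tuple(iteration_qs),
        method=f"louvain-consensus(n_iterations={n_iterations}, threshold=0.5)",
        labels=net.atlas.region_labels,
    )


def participation_coefficient(
    net: WeightedNetwork, partition: Partition, weighted: bool = False
) -> np.ndarray:
    """PI_i = 1 - sum_m (kappa_im / k_i)^2 over modules m.

    ``kappa_im`` counts node i's edges into module m (or sums their
    weights when ``weighted=True``); isolated nodes get PI = 0.
    """
    assignment = np.asarray(partition.assignment)
    conn = (net.weights if weighted else (net.weights > 0)).astype(float)
    k = conn.sum(axis=1)
    pi = np.zeros(net.n_nodes)
    nz = k > 0
    for m in np.unique(assignment):
        kappa = conn[:, assignment == m].sum(axis=1)
        pi[nz] += (kappa[nz] / k[nz]) ** 2
    pi[nz] = 1.0 - pi[nz]
    return pi


def classify_hub(pi: float, convention: str = "table") -> str:
    """Classify a hub by participation index.

    Default convention: provincial if PI <= 0.3, connector if
    0.3 < PI <= 0.75, otherwise unclassified.  ``convention="text"``
    swaps the provincial and connector ranges.
    """
    if not 0 <= pi <= 1:
        raise ValueError(f"participation index {pi} outside [0, 1]")
    low, mid = ("provincial", "connector") if convention == "table" else ("connector", "provincial")
    if pi <= 0.3:
        return low
    if pi <= 0.75:
        return mid
    return "unclassified"


def identify_hubs(
    group_net: WeightedNetwork,
    partition: Partition,
    convention: str = "table",
) -> list[HubRecord]:
    """Hubs of a group-averaged network: value >= mean + 1 SD per basis.

    Degree and strength are evaluated independently over the network's
    nodes (sample SD); a degenerate SD of 0 yields no hubs.  Each record
    carries the node's module, PI, and provincial/connector class.
    """
    from .metrics import nodal_degree, nodal_strength

    pi = participation_coefficient(group_net, partition)
    records: list[HubRecord] = []
    for basis, values in (
        ("degree", nodal_degree(group_net).astype(float)),
        ("strength", nodal_strength(group_net)),
    ):
        mean, sd = values.mean(), values.std(ddof=1)
        if sd == 0:
            continue
        for i in np.flatnonzero(values >= mean + sd):
            records.append(
                HubRecord(
                    node=group_net.atlas.region_labels[i],
                    basis=basis,
                    value=float(values[i]),
                    module=int(partition.assignment[i]),
                    participation=float(pi[i]),
                    klass=classify_hub(float(pi[i]), convention),
                )
            )
    return records


def match_modules(partition_a: Partition, partition_b: Partition) -> dict[int, int]:
    """Maximum-overlap one-to-one module correspondence (optimal assignment).

    Returns a mapping from B's module ids to A's; modules of B without a
    counterpart in A (when B has more modules) map to -1.
    """
    a, b = np.asarray(partition_a.assignment), np.asarray(partition_b.assignment)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same node set")
    ids_a, ids_b = np.unique(a), np.unique(b)
    overlap = np.zeros((len(ids_b), len(ids_a)))
    for i, cb in enumerate(ids_b):
        for j, ca in enumerate(ids_a):
            overlap[i, j] = np.count_nonzero((b == cb) & (a == ca))
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {int(ids_b[r]): int(ids_a[c]) for r, c in zip(rows, cols)}
    for cb in ids_b:
        mapping.setdefault(int(cb), -1)
    return mapping


def module_migration(
    partition_a: Partition, partition_b: Partition
) -> tuple[list[tuple[str, int, int]], dict[int, float]]:
    """Node migrations and signed percent module-size changes from A to B.

    Modules are matched first; per matched module the change is
    ``(size_B - size_A) / size_A * 100``.  Returns ``(migrations,
    size_changes)`` with migrations as (node label, from-module-in-A,
    to-module-in-A-ids).
    """
    mapping = match_modules(partition_a, partition_b)
    a = np.asarray(partition_a.assignment)
    b_in_a = np.array([mapping[int(c)] for c in partition_b.assignment])
    labels = partition_a.labels or tuple(str(i) for i in range(len(a)))
    migrations = [
        (labels[i], int(a[i]), int(b_in_a[i]))
        for i in np.flatnonzero(a != b_in_a)
    ]
    size_changes = {}
    for module in np.unique(a):
        size_a = int(np.count_nonzero(a == module))
        size_b = int(np.count_nonzero(b_in_a == module))
        size_changes[int(module)] = (size_b - size_a) / size_a * 100.0
    return migrations, size_changes


def compare_hubs(
    hubs_a: list[HubRecord],
    hubs_b: list[HubRecord],
    partition_a: Partition | None = None,
    partition_b: Partition | None = None,
) -> HubComparison:
    """Shared/gained/lost hubs (keyed by node and basis) and status changes.

    "Gained" means present in B but not A; "lost" the reverse.  Nodes
    that are hubs in both but switch provincial/connector class are
    listed as status changes.  When both partitions are given, module
    migrations and size changes are included.
    """
    key_a = {(h.node, h.basis): h for h in hubs_a}
    key_b = {(h.node, h.basis): h for h in hubs_b}
    shared = frozenset(key_a) & frozenset(key_b)
    gained = frozenset(key_b) - frozenset(key_a)
    lost = frozenset(key_a) - frozenset(key_b)
    status_changes = tuple(
        (node, basis, key_a[(node, basis)].klass, key_b[(node, basis)].klass)
        for node, basis in sorted(shared)
        if key_a[(node, basis)].klass != key_b[(node, basis)].klass
    )
    migrations: tuple = ()
    size_changes: dict = {}
    if partition_a is not None and partition_b is not None:
        mig, size_changes = module_migration(partition_a, partition_b)
        migrations = tuple(mig)
    return HubComparison(
        shared=shared,
        gained=gained,
        lost=lost,
        status_changes=status_changes,
        module_migrations=migrations,
        module_size_changes=size_changes,
    )
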