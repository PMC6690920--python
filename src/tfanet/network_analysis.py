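"""Three-layer network assembly, topology statistics, and validation tests.

The assembled network has modulators → TFs (modulation edges) and
TFs → targets (regulation edges); a gene may hold several roles. Topology is
computed with networkx (betweenness, degrees). Two statistical procedures
from the pipeline's validation stage live here as well: the bootstrap test
that inferred TF activity carries more information about a target than the
TF's own mRNA, and the context-specific rewiring analysis that bins samples
by a modulator's expression and tests whether the pairwise correlation
profile differs between bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .data_io import ExpressionMatrix
from .mi_inference import kernel_mi
from .modulation import conditional_mi, permutation_pvalue

logger = logging.getLogger(__name__)

REGULATION = "regulation"
MODULATION = "modulation"


@dataclass
class TFANetwork:
    """Directed three-layer graph: modulators → TFs → targets."""

    graph: nx.MultiDiGraph

    @property
    def modulators(self) -> set:
        return {n for n, d in self.graph.nodes(data=True) if "modulator" in d["roles"]}

    @property
    def tfs(self) -> set:
        return {n for n, d in self.graph.nodes(data=True) if "tf" in d["roles"]}

    @property
    def targets(self) -> set:
        return {n for n, d in self.graph.nodes(data=True) if "target" in d["roles"]}

    def edges_of_type(self, edge_type: str) -> list:
        return [(u, v) for u, v, k in self.graph.edges(keys=True) if k == edge_type]

    def summary(self) -> dict:
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_modulators": len(self.modulators),
            "n_tfs": len(self.tfs),
            "n_targets": len(self.targets),
            "n_regulation_edges": len(self.edges_of_type(REGULATION)),
            "n_modulation_edges": len(self.edges_of_type(MODULATION)),
        }


@dataclass
class RewiringResult:
    """Per-bin correlation profile of a gene pair along a modulator gradient."""

    gene_a: str
    gene_b: str
    modulator: str
    pcc_per_bin: np.ndarray
    category_per_bin: list
    cmi: float
    p_value: float
    bin_edges: list = field(default_factory=list)


def assemble_three_layer(pairs, active_triplets, weights_a=None,
                         weights_b=None) -> TFANetwork:
    """Build the deduplicated three-layer network from pairs and triplets.

    ``weights_a`` / ``weights_b`` optionally map (tf, target) / (modulator,
    tf) to fitted strengths, stored as edge weights.
    """
    g = nx.MultiDiGraph()

    def add_role(node, role):
        if node not in g:
            g.add_node(node, roles=set())
        g.nodes[node]["roles"].add(role)

    for p in pairs:
        add_role(p.tf, "tf")
        add_role(p.target, "target")
        if not g.has_edge(p.tf, p.target, key=REGULATION):
            w = weights_a.get((p.tf, p.target)) if weights_a else None
            g.add_edge(p.tf, p.target, key=REGULATION, mi=p.mi, weight=w)
    seen_mod = set()
    for t in active_triplets:
        add_role(t.modulator, "modulator")
        add_role(t.tf, "tf")
        add_role(t.target, "target")
        if (t.modulator, t.tf) not in seen_mod:
            seen_mod.add((t.modulator, t.tf))
            w = weights_b.get((t.modulator, t.tf)) if weights_b else None
            g.add_edge(t.modulator, t.tf, key=MODULATION, weight=w)
    net = TFANetwork(g)
    logger.info("assemble_three_layer: %s", net.summary())
    return net


def node_betweenness(net: TFANetwork, restrict_to_tfs: bool = False,
                     directed: bool = True) -> dict:
    """Unnormalized shortest-path betweenness, optionally on the TF core.

    With ``restrict_to_tfs`` the statistic is computed on the induced
    subgraph over TF-role nodes only (the "core" network of TFs regulating
    or modulating each other).
    """
    g = net.graph
    if restrict_to_tfs:
        g = g.subgraph(net.tfs)
    simple = nx.DiGraph(g) if directed else nx.Graph(g)
    if simple.number_of_nodes() == 0:
        return {}
    return nx.betweenness_centrality(simple, normalized=False)


def degree_summary(net: TFANetwork) -> dict:
    """Per-node in/out degree split by edge type, plus distribution counts."""
    per_node: dict = {}
    for node in net.graph.nodes:
        per_node[node] = {
            "in_regulation": 0, "out_regulation": 0,
            "in_modulation": 0, "out_modulation": 0,
        }
    for u, v, k in net.graph.edges(keys=True):
        per_node[u][f"out_{k}"] += 1
        per_node[v][f"in_{k}"] += 1
    mod_out = [per_node[m]["out_modulation"] for m in net.modulators]
    summary = {
        "per_node": per_node,
        "modulators_single_tf_fraction": (
            float(np.mean([d == 1 for d in mod_out])) if mod_out else float("nan")
        ),
    }
    return summary


def mi_improvement_test(tf_mrna, tfa, target, n_boot: int = 1000,
                        seed: int | None = None) -> tuple[float, float, float]:
    """Bootstrap test that activity beats mRNA in MI with a target.

    Resamples the samples with replacement, recomputes both MI scores
    jointly per replicate, and reports p = add-one fraction of replicates
    where the activity MI fails to exceed the mRNA MI (exact ties count
    half, so exchangeable inputs give p ≈ 0.5).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    tf_mrna = np.asarray(tf_mrna, dtype=float)
    tfa = np.asarray(tfa, dtype=float)
    target = np.asarray(target, dtype=float)
    if not (tf_mrna.shape == tfa.shape == target.shape):
        raise ValueError("vectors must have equal lengths")
    mi_mrna = kernel_mi(tf_mrna, target)
    mi_tfa = kernel_mi(tfa, target)
    rng = np.random.default_rng(seed)
    n = tf_mrna.size
    worse = 0.0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.ptp(tf_mrna[idx]) == 0 or np.ptp(tfa[idx]) == 0 \
                or np.ptp(target[idx]) == 0:
            worse += 1.0  # degenerate resample counts against improvement
            continue
        boot_tfa = kernel_mi(tfa[idx], target[idx])
        boot_mrna = kernel_mi(tf_mrna[idx], target[idx])
        if boot_tfa < boot_mrna:
            worse += 1.0
        elif boot_tfa == boot_mrna:
            worse += 0.5
    p = (1 + worse) / (1 + n_boot)
    return float(mi_mrna), float(mi_tfa), float(p)


def _two_means_1d(values: np.ndarray) -> list:
    """Deterministic 1-D 2-means: centroids initialised at min and max."""
    v = values.reshape(-1, 1)
    init = np.array([[values.min()], [values.max()]])
    if values.min() == values.max():
        return ["low"] * values.size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=2, init=init, n_init=1).fit(v)
    means = [values[km.labels_ == c].mean() for c in (0, 1)]
    high_cluster = int(np.argmax(means))
    return ["high" if lab == high_cluster else "low" for lab in km.labels_]


def rewiring_analysis(
    expr: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    modulator: str,
    n_bins: int = 10,
    n_perm: int = 10000,
    seed: int | None = None,
    fraction: float = 0.35,
) -> RewiringResult:
    """Context-specific rewiring of a gene pair along a modulator gradient.

    Samples are sorted by the modulator and split into ``n_bins`` equal-size
    groups (remainder in the last bin); the pair's Pearson correlation is
    computed per bin and the bin profile is categorised low/high by
    deterministic 1-D 2-means. Significance of the modulator's effect is the
    permutation p-value of the CMI (top/bottom ``fraction`` split).
    """
    a = expr.row(gene_a)
    b = expr.row(gene_b)
    m = expr.row(modulator)
    M = a.size
    if np.ptp(m) == 0:
        raise ValueError("constant modulator")
    if M < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} samples for {n_bins} bins")
    order = np.argsort(m, kind="stable")
    size = M // n_bins
    pccs = np.empty(n_bins)
    for i in range(n_bins):
        sel = order[i * size:] if i == n_bins - 1 else order[i * size:(i + 1) * size]
        if np.ptp(a[sel]) == 0 or np.ptp(b[sel]) == 0:
            logger.warning("rewiring: constant gene values in bin %d; PCC set to 0", i)
            pccs[i] = 0.0
        else:
            pccs[i] = stats.pearsonr(a[sel], b[sel]).statistic
    categories = _two_means_1d(pccs)
    _, _, cmi = conditional_mi(a, b, m, fraction)
    p = permutation_pvalue(a, b, m, n_perm=n_perm, seed=seed, fraction=fraction)
    return RewiringResult(gene_a, gene_b, modulator, pccs, categories,
                          float(cmi), p)
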