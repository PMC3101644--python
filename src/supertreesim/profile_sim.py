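"""Simulation of source-tree profiles with controlled taxon sampling.

The generator follows the standard supertree benchmarking pipeline:

1. a model tree on ``n`` taxa from a pure-birth (Yule) process, deviated
   from the molecular clock by i.i.d. lognormal branch-length multipliers;
2. genes assigned to subtrees by a gene gain/loss process (gain on one
   edge, Poisson losses below it), producing biologically shaped missing
   data; sequences evolved along each gene's subtree under GTR+Gamma+I
   without indels (the true alignment is known);
3. datasets assembled as one *scaffold* (a random sample of a fraction
   ``p`` of all taxa — the scaffold density — carrying 4 genes) plus many
   *clade-based* datasets (all leaves of a random rooted subtree, 3 genes
   each), or as all-scaffold profiles;
4. a source tree estimated per dataset from the concatenated genes
   (built-in: neighbor joining on corrected distances; hooks for an
   external maximum-likelihood program, or the true restricted tree).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import random as _random
import shlex
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
from dendropy.model import birthdeath

from . import treekit
from .treekit import PhyloTree, bipartition_set, restrict

__all__ = [
    "ModelCondition",
    "GTRModel",
    "Alignment",
    "Dataset",
    "SourceTree",
    "SourceTreeProfile",
    "simulate_model_tree",
    "assign_gene_leafsets",
    "evolve_sequences",
    "assemble_datasets",
    "estimate_source_tree",
    "build_profile",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
MISSING = -1


# ---------------------------------------------------------------------------
# conditions and models


@dataclasses.dataclass
class ModelCondition:
    """One cell of the benchmark design.

    ``scaffold_density`` is the fraction of the full taxon set placed in a
    scaffold dataset; ``profile_type`` selects mixed profiles (one scaffold
    plus clade-based datasets) or all-scaffold profiles.
    """

    n: int
    scaffold_density: float = 1.0
    profile_type: str = "mixed"
    n_replicates: int = 30
    # tree process
    birth_rate: float = 1.0
    deviation_sd: float = 0.5
    tree_height: float = 1.0
    # gene process
    loss_rate: float = 0.4
    min_gene_leaves: int = 4
    sites_per_gene: int = 500
    genes_per_scaffold: int = 4
    genes_per_clade: int = 3
    # profile shape
    n_clade_datasets: int | None = None
    clade_size_min: int = 5
    clade_size_max: int | None = None
    # estimation
    estimator: str = "nj"
    gtr_preset: str = "default"

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("need n >= 4 taxa")
        if not (0 < self.scaffold_density <= 1):
            raise ValueError("scaffold density must be in (0, 1]")
        if self.profile_type not in ("mixed", "all-scaffold"):
            raise ValueError("profile type must be 'mixed' or 'all-scaffold'")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.n_clade_datasets is None:
            self.n_clade_datasets = max(4, self.n // 5)
        if self.clade_size_max is None:
            self.clade_size_max = max(self.clade_size_min, math.ceil(self.n / 2))

    @property
    def n_datasets(self) -> int:
        return 1 + self.n_clade_datasets

    @property
    def condition_id(self) -> str:
        pct = int(round(100 * self.scaffold_density))
        return f"n{self.n}-d{pct}-{self.profile_type}"


@dataclasses.dataclass
class GTRModel:
    """General Time Reversible substitution model with Gamma-distributed
    site rates and a proportion of invariable sites.

    ``rates`` are the six exchangeabilities (AC, AG, AT, CG, CT, GT);
    the rate matrix is rescaled to one expected substitution per unit
    branch length (at site rate 1).
    """

    rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 1.0
    p_inv: float = 0.0

    def __post_init__(self):
        self.rates = tuple(float(r) for r in self.rates)
        self.freqs = tuple(float(f) for f in self.freqs)
        if len(self.rates) != 6 or any(r < 0 for r in self.rates):
            raise ValueError("need 6 non-negative exchangeability rates")
        if len(self.freqs) != 4 or abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if not (0 <= self.p_inv < 1):
            raise ValueError("invariable proportion must be in [0, 1)")

    @classmethod
    def preset(cls, name: str) -> "GTRModel":
        try:
            return cls(**PRESETS[name])
        except KeyError:
            raise ValueError(
                f"unknown GTR preset {name!r}; choose from {sorted(PRESETS)}"
            ) from None

    def rate_matrix(self) -> np.ndarray:
        """Normalized instantaneous rate matrix Q."""
        s = np.zeros((4, 4))
        iu = np.triu_indices(4, k=1)
        s[iu] = self.rates
        s = s + s.T
        pi = np.asarray(self.freqs)
        Q = s * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        return Q / scale

    def eigensystem(self):
        """Symmetrized eigendecomposition: Q = U diag(lam) V."""
        pi = np.asarray(self.freqs)
        sq = np.sqrt(pi)
        B = np.diag(sq) @ self.rate_matrix() @ np.diag(1.0 / sq)
        lam, W = np.linalg.eigh((B + B.T) / 2.0)
        U = np.diag(1.0 / sq) @ W
        V = W.T @ np.diag(sq)
        return lam, U, V


#: Named GTR+Gamma+I parameter presets (plausible empirical-style values;
#: configurable stand-ins, not tied to any particular published estimate).
PRESETS = {
    "default": dict(
        rates=(1.55, 4.09, 1.28, 0.90, 4.96, 1.0),
        freqs=(0.30, 0.21, 0.21, 0.28),
        alpha=1.0,
        p_inv=0.2,
    ),
    "jc": dict(
        rates=(1.0,) * 6,
        freqs=(0.25,) * 4,
        alpha=1.0,
        p_inv=0.0,
    ),
}


# ---------------------------------------------------------------------------
# alignments


class Alignment:
    """DNA alignment: taxa x sites, integer-coded (A,C,G,T = 0..3,
    missing = -1)."""

    def __init__(self, taxa: Sequence[str], data: np.ndarray):
        self.taxa = list(taxa)
        self.data = np.asarray(data, dtype=np.int8)
        if self.data.shape[0] != len(self.taxa):
            raise ValueError("row count does not match taxon count")

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def to_fasta(self) -> str:
        chunks = []
        lookup = np.array(list(BASES + "?"))
        for i, name in enumerate(self.taxa):
            seq = "".join(lookup[self.data[i]])
            chunks.append(f">{name}\n{seq}\n")
        return "".join(chunks)

    @classmethod
    def from_fasta(cls, text: str) -> "Alignment":
        from io import StringIO

        from Bio import SeqIO

        taxa, rows = [], []
        code = {b: i for i, b in enumerate(BASES)}
        for rec in SeqIO.parse(StringIO(text), "fasta"):
            taxa.append(rec.id)
            rows.append([code.get(ch, MISSING) for ch in str(rec.seq).upper()])
        return cls(taxa, np.array(rows, dtype=np.int8))

    @staticmethod
    def concatenate(alignments: Sequence["Alignment"], taxa: Sequence[str]) -> "Alignment":
        """Concatenate gene alignments over a common taxon list; taxa
        absent from a gene get missing characters for that block."""
        taxa = list(taxa)
        blocks = []
        for aln in alignments:
            block = np.full((len(taxa), aln.n_sites), MISSING, dtype=np.int8)
            for i, name in enumerate(taxa):
                if name in aln.taxa:
                    block[i] = aln.data[aln.taxa.index(name)]
            blocks.append(block)
        return Alignment(taxa, np.concatenate(blocks, axis=1))


# ---------------------------------------------------------------------------
# Step 1: model trees


def simulate_model_tree(
    n: int,
    birth_rate: float = 1.0,
    deviation_sd: float = 0.5,
    seed: int = 0,
    *,
    height: float | None = 1.0,
) -> PhyloTree:
    """Rooted binary model tree from a pure-birth process.

    The Yule tree is rescaled so the root-to-tip height equals ``height``
    (expected substitutions per site), then each branch length is
    multiplied by an independent lognormal factor with log-sd
    ``deviation_sd`` (0 keeps the tree ultrametric).  Leaves are labelled
    ``T01..Tn`` (zero-padded, so lexicographic equals numeric order).
    """
    if n < 4:
        raise ValueError("need n >= 4 leaves")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n,
        rng=rng,
    )
    # the simulation stops at the n-th birth, leaving the newest pair of
    # tips with zero-length branches; extend all tips by the waiting time
    # to the next (uncommitted) birth event so the tree stays ultrametric
    extra = rng.expovariate(n * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = len(str(n))
    for i, leaf in enumerate(tree.leaf_node_iter(), 1):
        leaf.taxon.label = f"T{i:0{width}d}"
    if height is not None:
        depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= height / depth
    nprng = np.random.default_rng(seed)
    if deviation_sd > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= float(nprng.lognormal(0.0, deviation_sd))
    tree.is_rooted = True
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Step 2: gene gain/loss and sequence evolution


def assign_gene_leafsets(
    tree: PhyloTree,
    n_genes: int,
    loss_rate: float = 0.4,
    min_leaves: int = 4,
    seed: int = 0,
    *,
    stem_weight: float | None = None,
    gain_at_root: bool = False,
) -> list[frozenset]:
    """Leaf sets of ``n_genes`` genes under a gain/loss process.

    Each gene is gained on one edge of the rooted model tree, sampled
    proportionally to branch length (a virtual stem edge above the root,
    of weight ``stem_weight``, allows genes present in all taxa; the
    default weight is half the total tree length).  Below the gain edge,
    each edge independently suffers Poisson losses at ``loss_rate`` per
    unit length; any edge with a loss prunes its subtree.  Genes with
    fewer than ``min_leaves`` surviving leaves are resampled.
    """
    n = tree.n_leaves
    if min_leaves > n:
        raise ValueError(f"minimum leaves {min_leaves} exceeds taxon count {n}")
    dt = tree.dendropy_tree
    root = dt.seed_node
    edges = [e for e in dt.preorder_edge_iter() if e.tail_node is not None]
    lengths = np.array([e.length or 0.0 for e in edges])
    if stem_weight is None:
        stem_weight = lengths.sum() / 2.0
    weights = np.concatenate([[stem_weight], lengths])
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)

    out = []
    for _ in range(n_genes):
        for _attempt in range(1000):
            if gain_at_root:
                gain_node = root
            else:
                k = int(rng.choice(len(weights), p=weights))
                gain_node = root if k == 0 else edges[k - 1].head_node
            survivors: set = set()

            def walk(node):
                for child in node.child_nodes():
                    ln = child.edge.length or 0.0
                    if rng.poisson(loss_rate * ln) > 0:
                        continue  # lost: prune the whole subtree
                    if child.is_leaf():
                        survivors.add(child.taxon.label)
                    else:
                        walk(child)

            if gain_node.is_leaf():
                survivors = {gain_node.taxon.label}
            else:
                walk(gain_node)
            if len(survivors) >= min_leaves:
                out.append(frozenset(survivors))
                break
        else:
            raise RuntimeError(
                "could not sample a gene leaf set meeting the minimum size"
            )
    return out


def evolve_sequences(
    tree: PhyloTree,
    model: GTRModel,
    length: int,
    seed: int = 0,
) -> Alignment:
    """Evolve a gapless DNA alignment down a tree with branch lengths.

    The root sequence is drawn from the stationary frequencies; each site
    is invariable with probability ``p_inv`` and otherwise carries a
    Gamma(alpha)-distributed rate (mean 1); substitutions follow the GTR
    transition probabilities of rate x branch length.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = np.random.default_rng(seed)
    pi = np.asarray(model.freqs)
    lam, U, V = model.eigensystem()

    site_rates = rng.gamma(model.alpha, 1.0 / model.alpha, size=length)
    if model.p_inv > 0:
        site_rates[rng.random(length) < model.p_inv] = 0.0

    dt = tree.dendropy_tree
    root = dt.seed_node
    states: dict = {root: _draw_categorical(rng, np.tile(pi, (length, 1)))}
    for node in dt.preorder_node_iter():
        if node is root:
            continue
        t_e = node.edge.length or 0.0
        parent = states[node.parent_node]
        if t_e == 0.0:
            states[node] = parent.copy()
            continue
        # per-site transition rows: row parent_state of exp(Q * t_e * r_s)
        E = np.exp(np.outer(site_rates, lam) * t_e)  # (sites, 4)
        probs = (U[parent] * E) @ V  # (sites, 4)
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1, keepdims=True)
        states[node] = _draw_categorical(rng, probs)

    taxa, rows = [], []
    for lf in dt.leaf_node_iter():
        taxa.append(lf.taxon.label)
        rows.append(states[lf])
    return Alignment(taxa, np.array(rows, dtype=np.int8))


def _draw_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """One draw per row of a (m, k) probability matrix."""
    u = rng.random(probs.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int8)


# ---------------------------------------------------------------------------
# Step 3: dataset assembly


@dataclasses.dataclass
class Dataset:
    """A taxon set with its gene alignments, tagged scaffold or clade."""

    name: str
    tag: str  # "scaffold" | "clade"
    taxa: frozenset
    genes: list  # list[Alignment]

    def concatenated(self) -> Alignment:
        return Alignment.concatenate(self.genes, sorted(self.taxa))


def assemble_datasets(
    model_tree: PhyloTree,
    condition: ModelCondition,
    seed: int = 0,
) -> list[Dataset]:
    """Assemble scaffold and clade-based datasets for one replicate.

    The scaffold dataset is a uniform sample of ``round(p * n)`` taxa with
    4 genes; each clade dataset is the leaf set of a random rooted subtree
    whose size falls in the configured range, with 3 genes.  Genes are
    simulated (gain/loss, then GTR+Gamma+I evolution) on the model tree
    restricted to the dataset's taxa, and the dataset keeps only taxa
    covered by at least one of its genes.
    """
    n = condition.n
    n_scaffold_taxa = int(round(condition.scaffold_density * n))
    if n_scaffold_taxa < 4:
        raise ValueError(
            f"scaffold of {n_scaffold_taxa} taxa is too small (need >= 4); "
            "increase the scaffold density"
        )
    rng = np.random.default_rng(seed)
    model = GTRModel.preset(condition.gtr_preset)
    all_taxa = sorted(model_tree.leaves)

    clade_nodes = [
        node
        for node in model_tree.dendropy_tree.preorder_node_iter()
        if not node.is_leaf()
        and condition.clade_size_min
        <= len(node.leaf_nodes())
        <= condition.clade_size_max
    ]

    def make_dataset(name: str, tag: str, taxa: frozenset, n_genes: int) -> Dataset:
        sub = restrict(model_tree, taxa)
        # scaffold datasets use universal markers (genes gained at the root
        # of the dataset's subtree, subject to loss) so that sparse samples
        # of the full taxon set still overlap; clade genes follow the full
        # gain/loss process
        gene_sets = assign_gene_leafsets(
            sub,
            n_genes,
            loss_rate=condition.loss_rate,
            min_leaves=condition.min_gene_leaves,
            seed=int(rng.integers(2**31)),
            gain_at_root=(tag == "scaffold"),
        )
        genes = [
            evolve_sequences(
                restrict(sub, gs) if len(gs) < len(taxa) else sub,
                model,
                condition.sites_per_gene,
                seed=int(rng.integers(2**31)),
            )
            for gs in gene_sets
        ]
        covered = frozenset().union(*(set(a.taxa) for a in genes))
        return Dataset(name, tag, covered, genes)

    datasets = []
    if condition.profile_type == "mixed":
        scaffold_taxa = frozenset(
            rng.choice(all_taxa, size=n_scaffold_taxa, replace=False)
        )
        datasets.append(
            make_dataset(
                "scaffold", "scaffold", scaffold_taxa, condition.genes_per_scaffold
            )
        )
        if not clade_nodes:
            raise ValueError(
                "no rooted subtree falls in the configured clade size range"
            )
        for i in range(condition.n_clade_datasets):
            node = clade_nodes[int(rng.integers(len(clade_nodes)))]
            taxa = frozenset(lf.taxon.label for lf in node.leaf_iter())
            datasets.append(
                make_dataset(f"clade{i + 1}", "clade", taxa, condition.genes_per_clade)
            )
    else:  # all-scaffold
        for i in range(condition.n_datasets):
            taxa = frozenset(
                rng.choice(all_taxa, size=n_scaffold_taxa, replace=False)
            )
            datasets.append(
                make_dataset(
                    f"scaffold{i + 1}", "scaffold", taxa, condition.genes_per_scaffold
                )
            )
    return datasets


# ---------------------------------------------------------------------------
# Step 4: source-tree estimation


def corrected_distance_matrix(aln: Alignment) -> np.ndarray:
    """Jukes-Cantor-corrected pairwise distances with pairwise deletion.

    Saturated pairs (mismatch fraction >= 3/4, correction undefined) fall
    back to the uncorrected fraction with a logged warning.  Pairs sharing
    no sites (possible when genes cover disjoint taxon subsets) are
    imputed through intermediate taxa (min-plus closure), so the matrix
    stays tree-like rather than receiving arbitrary constants.
    """
    X = aln.data
    m = X.shape[0]
    D = np.zeros((m, m))
    saturated = 0
    missing_pairs = []
    for i in range(m):
        for j in range(i + 1, m):
            valid = (X[i] >= 0) & (X[j] >= 0)
            nv = int(valid.sum())
            if nv == 0:
                D[i, j] = D[j, i] = np.nan
                missing_pairs.append((i, j))
                continue
            p = float(((X[i] != X[j]) & valid).sum()) / nv
            if p >= 0.74999:
                saturated += 1
                d = p
            else:
                d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    if saturated:
        logger.warning(
            "%d saturated pairs: correction undefined, used uncorrected distance",
            saturated,
        )
    if missing_pairs:
        logger.warning(
            "%d taxon pairs share no sites; distances imputed via "
            "intermediate taxa",
            len(missing_pairs),
        )
        _impute_missing_distances(D)
    return D


def _impute_missing_distances(D: np.ndarray) -> None:
    """Fill NaN entries with min over k of D[i,k] + D[k,j], iterating so
    chains of missing pairs resolve; symmetric in place."""
    m = D.shape[0]
    for _ in range(m):
        nans = np.argwhere(np.isnan(np.triu(D, k=1)))
        if not len(nans):
            return
        progressed = False
        for i, j in nans:
            via = D[i] + D[j]
            via[i] = via[j] = np.nan
            if np.all(np.isnan(via)):
                continue
            D[i, j] = D[j, i] = np.nanmin(via)
            progressed = True
        if not progressed:
            break
    # disconnected taxa (no path of shared sites): large fallback
    D[np.isnan(D)] = np.nanmax(D) * 2 if np.isfinite(np.nanmax(D)) else 5.0
    np.fill_diagonal(D, 0.0)


def estimate_source_tree(dataset: Dataset, estimator: str | dict = "nj") -> PhyloTree:
    """Estimate an unrooted binary tree from a dataset's concatenated genes.

    ``estimator`` is ``"nj"`` (built-in: neighbor joining on corrected
    distances) or a dict ``{"command": "..."}`` shelling out to an
    external ML program that reads a FASTA path (``{fasta}`` placeholder)
    and prints newick on stdout.
    """
    taxa = sorted(dataset.taxa)
    if len(taxa) < 4:
        raise ValueError(f"dataset {dataset.name} has fewer than 4 taxa")
    aln = dataset.concatenated()
    if isinstance(estimator, dict):
        return _external_ml(aln, estimator)
    if estimator != "nj":
        raise ValueError(f"unknown estimator {estimator!r}")
    return nj_tree(corrected_distance_matrix(aln), aln.taxa)


def nj_tree(D: np.ndarray, taxa: Sequence[str]) -> PhyloTree:
    """Neighbor joining on a distance matrix (scikit-bio implementation)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.asarray(D, dtype=float)
    D = (D + D.T) / 2.0  # exact symmetry despite float summation order
    tree = nj(DistanceMatrix(D, list(taxa)))
    return treekit.read_newick(str(tree))


def _external_ml(aln: Alignment, config: dict) -> PhyloTree:
    command = config["command"]
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "genes.fasta"
        fasta.write_text(aln.to_fasta())
        cmd = [part.format(fasta=str(fasta)) for part in shlex.split(command)]
        out = subprocess.run(cmd, capture_output=True, text=True, check=True).stdout
    return treekit.read_newick(out.strip().splitlines()[-1])


# ---------------------------------------------------------------------------
# profile container and orchestration


@dataclasses.dataclass
class SourceTree:
    """An estimated source tree with its dataset tag and edge count."""

    tree: PhyloTree
    tag: str
    name: str

    @property
    def taxa(self) -> frozenset:
        return self.tree.leaves

    @property
    def m_t(self) -> int:
        """Number of internal edges (non-trivial bipartitions)."""
        return len(bipartition_set(self.tree))


class SourceTreeProfile:
    """The profile of estimated source trees for one replicate."""

    def __init__(
        self,
        trees: Sequence[SourceTree],
        model_tree: PhyloTree | None = None,
        condition: ModelCondition | None = None,
        manifest: dict | None = None,
    ):
        if not trees:
            raise ValueError("a profile needs at least one source tree")
        self.trees = list(trees)
        self.model_tree = model_tree
        self.condition = condition
        self.manifest = manifest or {}
        if model_tree is not None:
            stray = self.taxa_union - model_tree.leaves
            if stray:
                raise ValueError(
                    f"source-tree taxa not in model tree: {sorted(stray)}"
                )

    @property
    def taxa_union(self) -> frozenset:
        return frozenset().union(*(st.taxa for st in self.trees))

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def build_profile(condition: ModelCondition, seed: int = 0):
    """Run the full simulation for one replicate.

    Returns ``(model_tree, profile)``; all randomness flows from ``seed``
    through named per-step streams recorded in ``profile.manifest``.  With
    ``condition.estimator == "true"`` estimation is skipped and each
    source tree is the model tree restricted to the dataset's taxa
    (the clean-recovery oracle mode).
    """
    ss = np.random.SeedSequence(seed)
    tree_seed, data_seed = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2)
    )
    model_tree = simulate_model_tree(
        condition.n,
        condition.birth_rate,
        condition.deviation_sd,
        seed=tree_seed,
        height=condition.tree_height,
    )
    datasets = assemble_datasets(model_tree, condition, seed=data_seed)
    source_trees = []
    for ds in datasets:
        if condition.estimator == "true":
            est = restrict(model_tree, ds.taxa)
        else:
            est = estimate_source_tree(ds, condition.estimator)
        source_trees.append(SourceTree(est, ds.tag, ds.name))
    manifest = {
        "condition": condition.condition_id,
        "seed": seed,
        "tree_seed": tree_seed,
        "data_seed": data_seed,
        "estimator": str(condition.estimator),
        "datasets": [
            {
                "name": ds.name,
                "tag": ds.tag,
                "taxa": sorted(ds.taxa),
                "n_genes": len(ds.genes),
                "sites_per_gene": condition.sites_per_gene,
            }
            for ds in datasets
        ],
    }
    profile = SourceTreeProfile(source_trees, model_tree, condition, manifest)
    return model_tree, profile


def write_profile_dir(path, model_tree: PhyloTree, profile: SourceTreeProfile) -> None:
    """Write a replicate directory: model tree, source trees, manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "model_tree.nwk").write_text(model_tree.to_newick() + "\n")
    lines = [st.tree.to_newick(lengths=False) for st in profile.trees]
    (path / "source_trees.nwk").write_text("\n".join(lines) + "\n")
    manifest = dict(profile.manifest)
    manifest["source_trees"] = [
        {"name": st.name, "tag": st.tag, "m_t": st.m_t} for st in profile.trees
    ]
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_profile_dir(path) -> SourceTreeProfile:
    """Load a replicate directory written by :func:`write_profile_dir`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    model_tree = treekit.read_newick((path / "model_tree.nwk").read_text())
    trees = treekit.read_newick_list((path / "source_trees.nwk").read_text())
    tags = manifest.get("source_trees") or [{}] * len(trees)
    records = [
        SourceTree(t, info.get("tag", "scaffold"), info.get("name", f"tree{i}"))
        for i, (t, info) in enumerate(zip(trees, tags))
    ]
    return SourceTreeProfile(records, model_tree, manifest=manifest)
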