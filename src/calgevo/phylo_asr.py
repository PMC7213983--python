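"""Marginal ancestral reconstruction, altAll ancestors, topology enumeration
and Fitch parsimony.

The statistical model is the 20-state equal-exchangeability (Poisson) amino
acid model with uniform equilibrium frequencies, optionally with discrete
gamma rate heterogeneity. Under this model the transition probability along a
branch of length ``b`` (expected substitutions/site) at relative rate ``r`` is

    P(same)      = 1/20 + (19/20) * exp(-(20/19) * r * b)
    P(different) = 1/20 * (1 - exp(-(20/19) * r * b))

Marginal posteriors at an internal node are computed with the pruning
recursion (conditional likelihoods up from the tips) followed by a
root-to-node "outside" pass, integrating over all other nodes. The altAll
ancestor swaps in the second-best state wherever its posterior probability
strictly exceeds a threshold (default 0.20), producing a worst-case
reconstruction for robustness checks.

An exhaustive-enumeration implementation of the same posteriors
(:func:`marginal_posteriors_enumeration`) is provided for validation; it sums
the joint probability over every assignment of states to internal nodes and
shares no code with the pruning path.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

from .alignment import AMINO_ACIDS, GAP, Alignment
from .trees import Node, PhyloTree, TreeError

K = len(AMINO_ACIDS)
_STATE_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

__all__ = [
    "ASRError",
    "PosteriorTable",
    "AltAllPolicy",
    "AncestorReconstruction",
    "TopologyComparison",
    "FitchResult",
    "transition_matrix",
    "gamma_rates",
    "marginal_asr",
    "marginal_posteriors_enumeration",
    "build_altall",
    "count_differences",
    "enumerate_clade_topologies",
    "n_rooted_topologies",
    "compare_across_topologies",
    "fitch_parsimony",
    "fitch_parsimony_bruteforce",
]


class ASRError(ValueError):
    pass


# --------------------------------------------------------------------- model


def transition_matrix(branch_length: float, rate: float = 1.0) -> np.ndarray:
    """Poisson-model transition probability matrix for one branch."""
    if branch_length < 0 or not np.isfinite(branch_length):
        raise ASRError(f"invalid branch length {branch_length}")
    e = np.exp(-(K / (K - 1)) * rate * branch_length)
    P = np.full((K, K), (1.0 - e) / K)
    np.fill_diagonal(P, 1.0 / K + (1.0 - 1.0 / K) * e)
    return P


def gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Median discretization of a mean-one gamma into equal-weight categories."""
    if shape <= 0 or n_categories < 1:
        raise ASRError("gamma shape and category count must be positive")
    q = (2 * np.arange(n_categories) + 1) / (2 * n_categories)
    rates = _gamma_dist.ppf(q, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


# ----------------------------------------------------------- posterior table


@dataclass
class PosteriorTable:
    """Per-site posterior probability vectors over the 20 states at one node.

    ``probs`` has shape (n_sites, 20) in the alphabetical state order of
    :data:`calgevo.alignment.AMINO_ACIDS`. Sites skipped because a descendant
    tip carries a gap hold NaN rows and are listed in ``gap_sites``
    (1-based, like every site index this package reports).
    """

    node: str
    probs: np.ndarray
    gap_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != K:
            raise ASRError("posterior table must be (n_sites, 20)")
        self.validate()

    def validate(self, atol: float = 1e-6) -> None:
        mask = self.site_mask
        p = self.probs[mask]
        if p.size and (np.any(p < -atol) or np.any(p > 1 + atol)):
            raise ASRError("posterior probabilities outside [0, 1]")
        if p.size:
            sums = p.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > atol)[0]
            if bad.size:
                site = np.where(mask)[0][bad[0]] + 1
                raise ASRError(
                    f"posterior row at site {site} sums to {sums[bad[0]]:.6f}, not 1"
                )

    @property
    def n_sites(self) -> int:
        return self.probs.shape[0]

    @property
    def site_mask(self) -> np.ndarray:
        """Boolean mask of non-gap sites."""
        return ~np.isnan(self.probs).any(axis=1)

    @property
    def ml_sequence(self) -> str:
        out = []
        for row in self.probs:
            out.append(GAP if np.isnan(row).any() else AMINO_ACIDS[int(np.argmax(row))])
        return "".join(out)

    @property
    def ml_posteriors(self) -> np.ndarray:
        """Posterior probability of the ML state per site (NaN at gap sites)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmax(self.probs, axis=1)

    @property
    def average_posterior(self) -> float:
        """Mean ML-state posterior over all non-gap sites."""
        mask = self.site_mask
        if not mask.any():
            raise ASRError("no non-gap sites")
        return float(self.probs[mask].max(axis=1).mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(AMINO_ACIDS))
        df.insert(0, "site", np.arange(1, self.n_sites + 1))
        df.insert(0, "node", self.node)
        return df[self.site_mask.tolist()].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, node: str | None = None) -> "PosteriorTable":
        if node is not None:
            df = df[df["node"] == node]
        elif df["node"].nunique() == 1:
            node = str(df["node"].iloc[0])
        else:
            raise ASRError("frame holds several nodes; pass node=")
        sites = df["site"].to_numpy(dtype=int)
        n_sites = int(sites.max())
        probs = np.full((n_sites, K), np.nan)
        probs[sites - 1] = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
        gap_sites = tuple(s for s in range(1, n_sites + 1) if s not in set(sites))
        return cls(node=node, probs=probs, gap_sites=gap_sites)


# ------------------------------------------------------------- marginal ASR


def _tip_conditionals(tree: PhyloTree, alignment: Alignment, sites: np.ndarray):
    """Indicator conditional likelihoods for the tips at the selected sites."""
    cond = {}
    for leaf in tree.leaves():
        if leaf.name not in alignment:
            raise ASRError(f"leaf {leaf.name!r} has no sequence in the alignment")
        seq = alignment[leaf.name]
        arr = np.zeros((sites.size, K))
        for row, s in enumerate(sites):
            arr[row, _STATE_INDEX[seq[s]]] = 1.0
        cond[leaf.name] = arr
    return cond


def marginal_asr(
    tree: PhyloTree,
    alignment: Alignment,
    gamma_shape: float | None = None,
    n_rate_categories: int = 4,
) -> dict[str, PosteriorTable]:
    """Marginal ancestral-state posteriors at every internal node.

    Sites where any tip of the tree carries a gap are skipped with a warning
    and reported as NaN rows / ``gap_sites`` in the returned tables; the ML
    sequence carries the gap symbol there. Returns a mapping from internal
    node name to its :class:`PosteriorTable`.
    """
    missing = [n for n in tree.leaf_names if n not in alignment]
    if missing:
        raise ASRError(f"leaves without sequences: {missing}")
    L = alignment.n_sites
    tip_seqs = {name: alignment[name] for name in tree.leaf_names}
    gap_sites = [
        s for s in range(L) if any(seq[s] == GAP for seq in tip_seqs.values())
    ]
    if gap_sites:
        warnings.warn(
            f"{len(gap_sites)} site(s) contain gaps and were skipped: "
            f"{[s + 1 for s in gap_sites]}",
            stacklevel=2,
        )
    sites = np.array([s for s in range(L) if s not in set(gap_sites)], dtype=int)

    rates = (
        np.array([1.0])
        if gamma_shape is None
        else gamma_rates(gamma_shape, n_rate_categories)
    )
    pi = np.full(K, 1.0 / K)

    n_internal = len(tree.internal_nodes())
    num = {n.name: np.zeros((sites.size, K)) for n in tree.internal_nodes()}
    denom = np.zeros(sites.size)

    tips = _tip_conditionals(tree, alignment, sites) if sites.size else {}
    for rate in rates:
        weight = 1.0 / rates.size
        P = {
            n.name: transition_matrix(n.length, rate)
            for n in tree.postorder()
            if n is not tree.root
        }
        # pruning pass: conditional likelihood of the subtree below each node
        down: dict[str, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                down[node.name] = tips[node.name]
            else:
                lik = np.ones((sites.size, K))
                for child in node.children:
                    lik *= down[child.name] @ P[child.name].T
                down[node.name] = lik
        # outside pass: likelihood of everything above/beside each node
        up: dict[str, np.ndarray] = {tree.root.name: np.tile(pi, (sites.size, 1))}
        for node in tree.postorder()[::-1]:
            for child in node.children:
                if child.is_leaf:
                    continue
                partial = up[node.name].copy()
                for sib in node.children:
                    if sib is not child:
                        partial *= down[sib.name] @ P[sib.name].T
                up[child.name] = partial @ P[child.name]
        if n_internal:
            site_lik = (down[tree.root.name] * up[tree.root.name]).sum(axis=1)
        else:  # degenerate single-leaf tree
            site_lik = np.full(sites.size, 1.0)
        denom += weight * site_lik
        for name in num:
            num[name] += weight * down[name] * up[name]

    tables = {}
    for node in tree.internal_nodes():
        probs = np.full((L, K), np.nan)
        if sites.size:
            probs[sites] = num[node.name] / denom[:, None]
        tables[node.name] = PosteriorTable(
            node=node.name,
            probs=probs,
            gap_sites=tuple(s + 1 for s in gap_sites),
        )
    return tables


def marginal_posteriors_enumeration(
    tree: PhyloTree,
    alignment: Alignment,
    site: int,
    gamma_shape: float | None = None,
    n_rate_categories: int = 4,
) -> dict[str, np.ndarray]:
    """Posteriors at one site by explicit summation over every assignment of
    states to the internal nodes (validation oracle; ``site`` is 1-based).

    Scales as 20^(number of internal nodes): use on small trees only.
    """
    s = site - 1
    internals = tree.internal_nodes()
    names = [n.name for n in internals]
    tip_state = {
        leaf.name: _STATE_INDEX[alignment[leaf.name][s]] for leaf in tree.leaves()
    }
    rates = (
        np.array([1.0])
        if gamma_shape is None
        else gamma_rates(gamma_shape, n_rate_categories)
    )
    edges = [
        (node.name, child.name, child.length)
        for node in tree.postorder()
        for child in node.children
    ]
    grids = np.meshgrid(*([np.arange(K)] * len(names)), indexing="ij")
    assign = {name: g.ravel() for name, g in zip(names, grids)}
    joint = np.zeros(K ** len(names))
    for rate in rates:
        P = {child: transition_matrix(bl, rate) for _, child, bl in edges}
        contrib = np.full(K ** len(names), 1.0 / (K * rates.size))
        for parent, child, _ in edges:
            child_states = (
                np.full_like(assign[names[0]], tip_state[child])
                if child in tip_state
                else assign[child]
            )
            contrib = contrib * P[child][assign[parent], child_states]
        joint += contrib
    total = joint.sum()
    return {
        name: np.bincount(assign[name], weights=joint, minlength=K) / total
        for name in names
    }


# ------------------------------------------------------------------- altAll


@dataclass(frozen=True)
class AltAllPolicy:
    """Threshold rule for the alternate ('worst-case') ancestor.

    A site is swapped to its second-best state when that state's posterior
    probability is *strictly* greater than ``threshold``.
    """

    threshold: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ASRError("altAll threshold must lie in (0, 1)")


@dataclass
class AncestorReconstruction:
    """Paired ML and altAll sequences for one ancestral node."""

    node: str
    ml_sequence: str
    altall_sequence: str
    ml_posteriors: np.ndarray
    average_posterior: float
    substituted_sites: tuple[int, ...]  # 1-based

    def __post_init__(self) -> None:
        if len(self.ml_sequence) != len(self.altall_sequence):
            raise ASRError("ML and altAll sequences differ in length")
        observed = tuple(
            i + 1
            for i, (a, b) in enumerate(zip(self.ml_sequence, self.altall_sequence))
            if a != b
        )
        if observed != tuple(self.substituted_sites):
            raise ASRError("substituted_sites inconsistent with the sequences")

    @property
    def n_substitutions(self) -> int:
        return len(self.substituted_sites)


def build_altall(
    table: PosteriorTable, policy: AltAllPolicy = AltAllPolicy()
) -> AncestorReconstruction:
    """Construct the altAll ancestor from one node's posterior table.

    At each non-gap site the runner-up state (best non-ML state,
    alphabetically first on ties) replaces the ML state when its posterior
    strictly exceeds the policy threshold; ties between ML and runner-up
    keep the ML state. Gap sites stay gaps.
    """
    table.validate()
    ml = table.ml_sequence
    alt = list(ml)
    substituted = []
    for i, row in enumerate(table.probs):
        if np.isnan(row).any():
            continue
        best = int(np.argmax(row))  # alphabetically first on exact ties
        masked = row.copy()
        masked[best] = -np.inf
        runner = int(np.argmax(masked))
        if row[runner] > policy.threshold and row[runner] < row[best]:
            alt[i] = AMINO_ACIDS[runner]
            substituted.append(i + 1)
        elif row[runner] > policy.threshold and row[runner] == row[best]:
            # exact PP tie with the ML state: keep ML
            pass
    return AncestorReconstruction(
        node=table.node,
        ml_sequence=ml,
        altall_sequence="".join(alt),
        ml_posteriors=table.ml_posteriors,
        average_posterior=table.average_posterior,
        substituted_sites=tuple(substituted),
    )


def count_differences(seq_a: str, seq_b: str) -> int:
    """Hamming distance between two aligned sequences (gap vs residue counts)."""
    if len(seq_a) != len(seq_b):
        raise ASRError(
            f"sequence lengths differ ({len(seq_a)} vs {len(seq_b)}); "
            "no implicit alignment is performed"
        )
    return sum(a != b for a, b in zip(seq_a, seq_b))


# ------------------------------------------------------ topology enumeration


def n_rooted_topologies(n: int) -> int:
    """(2n-3)!! — the number of rooted binary leaf-labeled topologies."""
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


def _insertions(shape, leaf):
    yield (shape, leaf)
    if isinstance(shape, tuple):
        left, right = shape
        for new_left in _insertions(left, leaf):
            yield (new_left, right)
        for new_right in _insertions(right, leaf):
            yield (left, new_right)


def _min_label(shape) -> str:
    return shape if isinstance(shape, str) else min(_min_label(c) for c in shape)


def _canonical(shape):
    if isinstance(shape, str):
        return shape
    children = sorted((_canonical(c) for c in shape), key=_min_label)
    return tuple(children)


def _shape_to_newick(shape) -> str:
    if isinstance(shape, str):
        return shape
    return "(" + ",".join(_shape_to_newick(c) for c in shape) + ")"


def enumerate_clade_topologies(clade_names: list[str]) -> list[PhyloTree]:
    """All distinct rooted binary leaf-labeled topologies over the names.

    Trees are deduplicated by a canonical form (children ordered by smallest
    descendant label) and returned sorted by their Newick string; branch
    lengths are left at 0. The count is (2n-3)!! for n names.
    """
    names = list(clade_names)
    if len(names) < 2:
        raise ASRError("need at least two clade names")
    if len(set(names)) != len(names):
        raise ASRError("duplicate clade names")
    shapes = [names[0]]
    for leaf in names[1:]:
        shapes = [new for shape in shapes for new in _insertions(shape, leaf)]
    canonical = sorted({_shape_to_newick(_canonical(s)) + ";" for s in shapes})
    return [PhyloTree.from_newick(nwk) for nwk in canonical]


@dataclass
class TopologyComparison:
    """Sequence differences of per-topology ancestors against a reference."""

    counts: dict[str, int]
    mean_differences: float
    union_sites: tuple[int, ...]  # 1-based union of differing sites
    within_altall_set: bool  # union ⊆ reference ML-vs-altAll differing sites

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"topology": list(self.counts), "n_differences": list(self.counts.values())}
        )


def compare_across_topologies(
    reconstructions: dict[str, str | AncestorReconstruction],
    reference: AncestorReconstruction,
) -> TopologyComparison:
    """Difference counts of topology-specific ancestors vs the reference ML
    ancestor, and whether all differing sites fall inside the reference's
    ML-vs-altAll substituted set."""
    if not reconstructions:
        raise ASRError("no reconstructions to compare")
    counts = {}
    union: set[int] = set()
    for key, recon in reconstructions.items():
        seq = recon.ml_sequence if isinstance(recon, AncestorReconstruction) else recon
        counts[key] = count_differences(seq, reference.ml_sequence)
        union |= {
            i + 1
            for i, (a, b) in enumerate(zip(seq, reference.ml_sequence))
            if a != b
        }
    return TopologyComparison(
        counts=counts,
        mean_differences=float(np.mean(list(counts.values()))),
        union_sites=tuple(sorted(union)),
        within_altall_set=union <= set(reference.substituted_sites),
    )


# ---------------------------------------------------------- Fitch parsimony


@dataclass
class FitchResult:
    """Fitch state sets per node and the minimum number of changes."""

    state_sets: dict[str, frozenset]
    root_states: frozenset
    n_changes: int


def fitch_parsimony(tree: PhyloTree, traits: dict[str, object]) -> FitchResult:
    """Fitch bottom-up pass for a binary (or any discrete) character.

    Child sets are intersected when the intersection is nonempty, otherwise
    unioned with one change counted. Every leaf must carry a state.
    """
    missing = [n for n in tree.leaf_names if n not in traits]
    if missing:
        raise ASRError(f"leaves without trait assignment: {missing}")
    sets: dict[str, frozenset] = {}
    changes = 0
    for node in tree.postorder():
        if node.is_leaf:
            sets[node.name] = frozenset([traits[node.name]])
        else:
            left, right = (sets[c.name] for c in node.children)
            inter = left & right
            if inter:
                sets[node.name] = inter
            else:
                sets[node.name] = left | right
                changes += 1
    return FitchResult(
        state_sets=sets, root_states=sets[tree.root.name], n_changes=changes
    )


def fitch_parsimony_bruteforce(tree: PhyloTree, traits: dict[str, object]) -> int:
    """Minimum change count by enumerating all internal labelings (oracle)."""
    states = sorted(set(traits.values()), key=repr)
    internals = [n.name for n in tree.internal_nodes()]
    edges = [
        (node.name, child.name)
        for node in tree.postorder()
        for child in node.children
    ]
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        label = dict(zip(internals, combo))
        label.update(traits)
        cost = sum(label[p] != label[c] for p, c in edges)
        best = cost if best is None else min(best, cost)
    return 0 if best is None else best
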