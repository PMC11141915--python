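"""Per-patient clone phylogenies from binary mutation presence patterns.

Each somatic mutation, after the somatic-call filter, defines the subset of
a patient's samples in which it is present.  Identical subsets are pooled
into *patterns*; a laminar (nested-or-disjoint) family of patterns is
exactly a rooted tree by containment, with branch lengths equal to the
number of mutations supporting each pattern — the number of shared/unique
nonsynonymous mutations.  Crossing patterns (the two-state analogue of the
three-gamete condition) are resolved by iteratively dropping the pattern
with the fewest supporting mutations ("drop-min").

Leaves carry sample metadata (subcategory, ploidy, metastasis); branches
carry mutation counts, driver labels, and — after annotation — arm-level
copy-number and WGD events placed on the MRCA branch of the carriers.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MutationPattern",
    "TreeNode",
    "PhyloTree",
    "build_pattern_matrix",
    "check_compatibility",
    "build_tree",
    "annotate_tree",
    "export_newick",
    "import_newick",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutationPattern:
    samples: frozenset[str]
    count: int
    drivers: tuple[str, ...] = ()
    mutation_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("pattern must cover at least one sample")
        if self.count < 1:
            raise ValueError("pattern count must be >= 1")


@dataclass
class TreeNode:
    name: str
    branch_length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    attrs: dict = field(default_factory=dict)
    is_leaf_sample: bool = False

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def leaf_samples(self) -> frozenset[str]:
        if self.is_leaf_sample:
            return frozenset([self.name])
        out: set[str] = set()
        for c in self.children:
            out |= c.leaf_samples()
        return frozenset(out)


@dataclass
class PhyloTree:
    root: TreeNode
    samples: tuple[str, ...]
    dropped_patterns: list[MutationPattern] = field(default_factory=list)

    def total_branch_length(self) -> float:
        return sum(n.branch_length for n in self.root.walk())

    def find(self, name: str) -> TreeNode:
        for n in self.root.walk():
            if n.name == name:
                return n
        raise KeyError(name)

    def path_length(self, name: str) -> float:
        """Sum of branch lengths from the root to the named node."""
        def rec(node: TreeNode, acc: float) -> float | None:
            acc += node.branch_length
            if node.name == name:
                return acc
            for c in node.children:
                r = rec(c, acc)
                if r is not None:
                    return r
            return None
        r = rec(self.root, 0.0)
        if r is None:
            raise KeyError(name)
        return r


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

def build_pattern_matrix(filtered: pd.DataFrame) -> list[MutationPattern]:
    """Group one patient's filtered mutations by identical presence pattern.

    ``filtered`` needs columns mutation_id, region (sample id) and
    optionally driver.  Ordered by pattern size descending, then lexically.
    """
    if filtered["region"].nunique() < 2:
        raise ValueError("need >= 2 samples to build patterns")
    dup = filtered.duplicated(subset=["mutation_id", "region"])
    if dup.any():
        bad = filtered.loc[dup, "mutation_id"].iloc[0]
        raise ValueError(f"duplicate mutation id {bad!r} within a sample")
    groups: dict[frozenset, dict] = {}
    for mid, grp in filtered.groupby("mutation_id"):
        pattern = frozenset(grp["region"])
        rec = groups.setdefault(pattern, {"count": 0, "drivers": [],
                                          "mutation_ids": []})
        rec["count"] += 1
        rec["mutation_ids"].append(str(mid))
        if "driver" in grp.columns:
            d = grp["driver"].iloc[0]
            if d and not pd.isna(d):
                rec["drivers"].append(str(d))
    patterns = [
        MutationPattern(samples=k, count=v["count"],
                        drivers=tuple(sorted(set(v["drivers"]))),
                        mutation_ids=tuple(sorted(v["mutation_ids"])))
        for k, v in groups.items()
    ]
    patterns.sort(key=lambda p: (-len(p.samples), tuple(sorted(p.samples))))
    return patterns


def check_compatibility(patterns: list[MutationPattern]
                        ) -> list[tuple[MutationPattern, MutationPattern]]:
    """Pairs of patterns that overlap without nesting (no containment tree
    exists unless this list is empty)."""
    conflicts = []
    for i, a in enumerate(patterns):
        for b in patterns[i + 1:]:
            inter = a.samples & b.samples
            if inter and not (a.samples <= b.samples or b.samples <= a.samples):
                conflicts.append((a, b))
    return conflicts


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def _drop_min_resolve(patterns: list[MutationPattern]
                      ) -> tuple[list[MutationPattern], list[MutationPattern]]:
    """Iteratively drop the conflicting pattern with the fewest mutations
    (ties: smaller pattern, then lexical) until the family is laminar."""
    current = list(patterns)
    dropped = []
    while True:
        conflicts = check_compatibility(current)
        if not conflicts:
            return current, dropped
        involved = {p for pair in conflicts for p in pair}
        victim = min(involved, key=lambda p: (p.count, len(p.samples),
                                              tuple(sorted(p.samples))))
        logger.info("drop-min: removing pattern %s (%d mutations)",
                    sorted(victim.samples), victim.count)
        current = [p for p in current if p is not victim]
        dropped.append(victim)


def build_tree(patterns: list[MutationPattern],
               sample_metadata: dict[str, dict] | None = None,
               policy: str = "drop-min") -> PhyloTree:
    """Containment (Hasse) tree over a laminar pattern family.

    Every sample attaches as a leaf under the smallest pattern containing
    it; the root is the all-sample pattern (created with count 0 when no
    mutation is shared by all samples).  ``sample_metadata`` maps sample id
    to leaf attributes (subcategory, ploidy, metastasis, ...).
    """
    sample_metadata = sample_metadata or {}
    samples = sorted(
        {s for p in patterns for s in p.samples} | set(sample_metadata))
    if len(samples) == 1:
        logger.warning("single-sample patient: degenerate two-node tree")
    if policy == "drop-min":
        kept, dropped = _drop_min_resolve(patterns)
    elif policy == "strict":
        conflicts = check_compatibility(patterns)
        if conflicts:
            raise ValueError(f"{len(conflicts)} incompatible pattern pairs")
        kept, dropped = list(patterns), []
    else:
        raise ValueError(f"unknown resolution policy {policy!r}")

    all_set = frozenset(samples)
    by_set: dict[frozenset, tuple[int, tuple[str, ...]]] = {
        p.samples: (p.count, p.drivers) for p in kept}
    if all_set not in by_set:
        by_set[all_set] = (0, ())  # synthetic MRCA branch, zero mutations

    sets = sorted(by_set, key=lambda s: (-len(s), tuple(sorted(s))))
    nodes: dict[frozenset, TreeNode] = {}
    for s in sets:
        count, drivers = by_set[s]
        nodes[s] = TreeNode(
            name="anc_" + "-".join(sorted(s)), branch_length=float(count),
            attrs={"pattern": sorted(s), "n_mutations": count,
                   "drivers": list(drivers)})
    root = nodes[all_set]
    for s in sets:
        if s == all_set:
            continue
        # parent: smallest strict superset
        supersets = [t for t in sets if s < t]
        parent = min(supersets, key=len)
        nodes[parent].children.append(nodes[s])
    for sample in samples:
        containing = [s for s in sets if sample in s]
        host = min(containing, key=len)
        leaf = TreeNode(name=sample, branch_length=0.0, is_leaf_sample=True,
                        attrs=dict(sample_metadata.get(sample, {})))
        nodes[host].children.append(leaf)
    for s in sets:  # deterministic child order: leaves after patterns, lexical
        nodes[s].children.sort(key=lambda n: (n.is_leaf_sample, n.name))
    return PhyloTree(root=root, samples=tuple(samples),
                     dropped_patterns=dropped)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _mrca_branch(tree: PhyloTree, carriers: frozenset[str]) -> TreeNode:
    """Deepest node whose clade contains every carrier sample."""
    best = tree.root
    changed = True
    while changed:
        changed = False
        for c in best.children:
            if carriers <= c.leaf_samples():
                best = c
                changed = True
                break
    return best


def annotate_tree(tree: PhyloTree,
                  timing_calls: list | None = None,
                  arm_calls_by_sample: dict[str, list] | None = None,
                  wgd_by_sample: dict[str, object] | None = None) -> PhyloTree:
    """Label branches with timing verdicts, arm-level CN events and WGD.

    Each event is placed on the MRCA branch of the samples carrying it; when
    the carrier set does not match a clade exactly the event attaches to the
    deepest branch containing all carriers, with a warning.
    """
    if timing_calls:
        for call in timing_calls:
            carriers = frozenset(
                s for s, rec in call.evidence.get("samples", {}).items())
            if not carriers:
                continue
            node = _mrca_branch(tree, carriers)
            node.attrs.setdefault("timing", []).append(
                {"gene": call.gene, "verdict": call.verdict})
    if arm_calls_by_sample:
        events: dict[tuple[str, str], set[str]] = {}
        for sample, calls in arm_calls_by_sample.items():
            for ac in calls:
                if ac.call != "neutral":
                    events.setdefault((ac.arm, ac.call), set()).add(sample)
        for (arm, call), carriers in sorted(events.items()):
            node = _mrca_branch(tree, frozenset(carriers))
            if node.leaf_samples() != frozenset(carriers):
                logger.warning(
                    "CN event %s %s carriers %s do not form a clade; "
                    "attached to deepest compatible branch", arm, call,
                    sorted(carriers))
            node.attrs.setdefault("cn_events", []).append(f"{arm}_{call}")
    if wgd_by_sample:
        carriers = frozenset(s for s, w in wgd_by_sample.items() if w.wgd)
        if carriers:
            node = _mrca_branch(tree, carriers)
            if node.leaf_samples() != carriers:
                logger.warning("WGD carriers %s do not form a clade",
                               sorted(carriers))
            node.attrs["wgd"] = True
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _esc(name: str) -> str:
    return name.replace(" ", "_").replace("|", ".")


def _newick_rec(node: TreeNode, attrs_out: dict) -> str:
    label = _esc(node.name)
    attrs_out[label] = dict(node.attrs, is_leaf_sample=node.is_leaf_sample,
                            name=node.name)
    comment = ""
    simple = {k: v for k, v in node.attrs.items()
              if isinstance(v, (str, int, float, bool)) and v != ""}
    if simple:
        comment = "[&" + ",".join(f"{k}={v}" for k, v in sorted(simple.items())) + "]"
    if node.children:
        inner = ",".join(_newick_rec(c, attrs_out) for c in node.children)
        return f"({inner}){label}:{node.branch_length:g}{comment}"
    return f"{label}:{node.branch_length:g}{comment}"


def export_newick(tree: PhyloTree) -> tuple[str, dict]:
    """Newick text (attributes echoed in [&...] comment blocks) plus a JSON
    sidecar holding the full per-node attribute map; the pair round-trips
    losslessly through :func:`import_newick`."""
    attrs: dict = {}
    text = _newick_rec(tree.root, attrs) + ";"
    sidecar = {
        "schema_version": 1,
        "samples": list(tree.samples),
        "dropped_patterns": [
            {"samples": sorted(p.samples), "count": p.count}
            for p in tree.dropped_patterns
        ],
        "nodes": attrs,
    }
    return text, sidecar


def import_newick(text: str, sidecar: dict | None = None) -> PhyloTree:
    """Rebuild a PhyloTree from Newick text (and optional sidecar)."""
    import dendropy

    clean = re.sub(r"\[&[^\]]*\]", "", text)
    dtree = dendropy.Tree.get(data=clean, schema="newick",
                              suppress_internal_node_taxa=False)
    node_attrs = (sidecar or {}).get("nodes", {})

    def convert(dnode) -> TreeNode:
        label = (dnode.taxon.label if dnode.taxon is not None
                 else dnode.label) or ""
        label = label.replace(" ", "_")
        rec = node_attrs.get(label, {})
        node = TreeNode(
            name=rec.get("name", label),
            branch_length=float(dnode.edge.length or 0.0),
            attrs={k: v for k, v in rec.items()
                   if k not in ("is_leaf_sample", "name")},
            is_leaf_sample=bool(rec.get("is_leaf_sample",
                                        dnode.is_leaf())),
        )
        for child in dnode.child_nodes():
            node.children.append(convert(child))
        return node

    root = convert(dtree.seed_node)
    samples = tuple((sidecar or {}).get(
        "samples", sorted(root.leaf_samples())))
    return PhyloTree(root=root, samples=samples)


def write_tree(tree: PhyloTree, newick_path, sidecar_path) -> None:
    text, sidecar = export_newick(tree)
    with open(newick_path, "w") as fh:
        fh.write(text + "\n")
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, default=str)
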