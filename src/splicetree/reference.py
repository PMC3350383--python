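"""The published dystrophin reference tree, encoded as a fixed classifier.

The final tree separating the 77 internal authentic dystrophin exons from
the 15 known cryptic exons tests eight of the 26 indexes: acceptor-site
maximum-entropy strength (ME3'ss <= 1.39 at the root), SF2/ASF binding-site
density (10.53), donor-site maximum-entropy strength (5.58), U1 snRNA
binding free energy (-2.6), silencer-hexamer density (4.45), donor-side GC
content (46.8), acceptor Shapiro score (0.79) and exon size (144).  Its
nine leaves categorize authentic exons into groups A-E and cryptic exons
into groups a-d.  The tree is shipped as data
(``data/reference_tree.json``) in the same JSON dialect used for induced
trees; group signatures (``data/group_signatures.tsv``) record each
group's high/low pattern over the eight tested indexes.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass
from typing import Optional

from .c45 import TreeNode, classify, iter_nodes
from .resources import ResourceBundle, load_resources

#: the two exon-size cut-offs reported for the small-exon group; the
#: node-by-node tree description gives 144, a later summary sentence 114
SIZE_CUTOFF_DEFAULT = 144.0
SIZE_CUTOFF_ALTERNATE = 114.0


def reference_tree(bundle: Optional[ResourceBundle] = None,
                   size_cutoff: float = SIZE_CUTOFF_DEFAULT) -> TreeNode:
    """Build the reference classifier from the bundled tree JSON.

    ``size_cutoff`` selects the SIZE threshold of the small-exon node
    (144 by default; 114 is the documented alternate reading).
    """
    bundle = bundle or load_resources()
    tree = TreeNode.from_dict(copy.deepcopy(bundle.reference_tree))
    if size_cutoff != SIZE_CUTOFF_DEFAULT:
        for node in iter_nodes(tree):
            if node.feature == "SIZE":
                node.threshold = float(size_cutoff)
    return tree


def classify_reference(v, tree: Optional[TreeNode] = None,
                       bundle: Optional[ResourceBundle] = None) -> tuple:
    """Route a feature vector through the reference tree.

    Returns ``(group_label, class, path)``; values equal to a threshold
    take the "yes" (<=) branch.  A missing feature on the realized path
    raises, naming the feature.
    """
    tree = tree if tree is not None else reference_tree(bundle)
    klass, group, path = classify(tree, v)
    return group, klass, path


def tree_summary(t: TreeNode) -> dict:
    """Structural counts derived by traversal (never hard-coded)."""
    internal = [n for n in iter_nodes(t) if not n.is_leaf]
    leaves = [n for n in iter_nodes(t) if n.is_leaf]
    return {
        "n_internal": len(internal),
        "n_leaves": len(leaves),
        "n_authentic_groups": sum(1 for n in leaves if n.klass == "authentic"),
        "n_cryptic_groups": sum(1 for n in leaves if n.klass == "cryptic"),
        "features_used": sorted({n.feature for n in internal}),
    }


# ---------------------------------------------------------------------------
# group signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSignature:
    """One group's high/low pattern over the tree's tested indexes:
    'H' means the group's path requires value > threshold at that
    feature's node, 'L' means <=, '-' means the feature is untested."""

    group: str
    klass: str
    n: int
    pattern: dict  # feature -> 'H' | 'L' | '-'


def load_signatures(bundle: Optional[ResourceBundle] = None) -> list:
    bundle = bundle or load_resources()
    sigs = []
    with open(bundle.signatures_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        feature_cols = [c for c in reader.fieldnames
                        if c not in ("group", "class", "n")]
        for row in reader:
            sigs.append(GroupSignature(
                group=row["group"], klass=row["class"], n=int(row["n"]),
                pattern={f: row[f] for f in feature_cols},
            ))
    return sigs


def leaf_paths(tree: TreeNode) -> dict:
    """Map each leaf's group label to its root-to-leaf conditions,
    as ``{feature: (threshold, 'L'|'H')}`` ('L' = yes/<= branch)."""
    paths = {}

    def walk(node, conds):
        if node.is_leaf:
            paths[node.group] = dict(conds)
            return
        walk(node.left, conds + [(node.feature, (node.threshold, "L"))])
        walk(node.right, conds + [(node.feature, (node.threshold, "H"))])

    walk(tree, [])
    return paths


def verify_signatures(tree: TreeNode, sigs) -> list:
    """Check every group signature against the tree's leaf paths.

    A signature matches when its H/L marks are exactly the branch
    directions of the leaf's path and every path feature is marked.
    Returns a list of human-readable mismatch strings (empty = all good).
    """
    paths = leaf_paths(tree)
    report = []
    for sig in sigs:
        if sig.group not in paths:
            report.append(f"group {sig.group}: no such leaf in tree")
            continue
        path = paths[sig.group]
        for feat, (thr, direction) in path.items():
            marked = sig.pattern.get(feat, "-")
            if marked == "-":
                report.append(
                    f"group {sig.group}: incomplete signature, path feature "
                    f"{feat} (threshold {thr:g}) unmarked"
                )
            elif marked != direction:
                report.append(
                    f"group {sig.group}: {feat} marked {marked} but path "
                    f"requires {direction}"
                )
        for feat, marked in sig.pattern.items():
            if marked != "-" and feat not in path:
                report.append(
                    f"group {sig.group}: {feat} marked {marked} but is not "
                    "tested on this group's path"
                )
    return report
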