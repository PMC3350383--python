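"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators are provided, because they can guarantee different things:

* :func:`simulate_feature_table` samples *feature vectors* uniformly
  inside per-group boxes built from the reference tree's branch
  conditions, so every record provably routes to its designated group.
  The default configuration emulates the study design: 77 authentic
  exons in groups A-E (30/1/42/2/2), 15 cryptic exons in groups a-d
  (4/5/2/4), plus two first/last-exon mimics with missing splice-site
  features on one side (94 records, 92 complete).

* :func:`simulate_exon_records` samples *sequences*: exon bodies with a
  target GC content and planted enhancer/silencer k-mers, consensus-like
  (authentic) or degenerate (cryptic) splice-site windows, and random
  intronic flanks.  Sequence space cannot guarantee exact reference-tree
  routing; it exercises the scanners and the end-to-end pipeline.

All randomness flows through one seeded generator; the seed is mandatory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .records import ExonRecord
from .reference import leaf_paths, reference_tree
from .resources import ResourceBundle, load_resources
from .tables import META_COLUMNS

#: plausible value ranges per index, used as box bounds for untested sides
FEATURE_RANGES = {
    "SH5'ss": (0.0, 1.0), "SH3'ss": (0.0, 1.0),
    "ME5'ss": (-15.0, 11.0), "ME3'ss": (-15.0, 14.0),
    "Ri5'ss": (-8.0, 18.0), "Ri3'ss": (-8.0, 24.0),
    "FE": (-12.0, 0.0),
    "RESE-D": (0.0, 15.0), "PESE-D": (0.0, 15.0),
    "FESS-D": (0.0, 12.0), "PESS-D": (0.0, 12.0),
    "SF2/ASF-N": (0, 12), "SF2/ASF(IgM,BRCA1)-N": (0, 12),
    "SRp40-N": (0, 12), "SC35-N": (0, 12), "SRp55-N": (0, 12),
    "SF2/ASF-D": (0.0, 25.0), "SF2/ASF(IgM,BRCA1)-D": (0.0, 20.0),
    "SC35-D": (0.0, 20.0), "SRp40-D": (0.0, 20.0), "SRp55-D": (0.0, 20.0),
    "RSS5'ss": (-60.0, -5.0), "RSS3'ss": (-60.0, -5.0),
    "GC5'ss": (20.0, 75.0), "GC3'ss": (20.0, 75.0),
    "SIZE": (30, 400),
}

_INT_FEATURES = frozenset(
    f for f in FEATURE_NAMES if f.endswith("-N") or f == "SIZE"
)

#: published per-group record counts of the reference tree's leaves
DEFAULT_GROUP_COUNTS = {
    "A": 30, "B": 1, "C": 42, "D": 2, "E": 2,
    "a": 4, "b": 5, "c": 2, "d": 4,
}


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    seed: int
    n_per_group: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS))
    margin_frac: float = 0.04
    feature_boxes: Optional[dict] = None  # per-group overrides
    n_missing_records: int = 2
    # sequence-space settings
    exon_len: tuple = (60, 220)
    flank_len: int = 90
    exon_gc: float = 0.48
    flank_gc: float = 0.40
    planted: dict = field(default_factory=lambda: {
        "authentic": {"ese": 4, "ess": 0},
        "cryptic": {"ese": 1, "ess": 5},
    })

    def __post_init__(self):
        if self.seed is None:
            raise SyntheticError("seed is mandatory")
        if self.margin_frac < 0:
            raise SyntheticError("margin_frac must be >= 0")
        if any(n < 0 for n in self.n_per_group.values()):
            raise SyntheticError("negative group count")
        if self.flank_len < 70:
            raise SyntheticError("flank_len must be >= 70")


# ---------------------------------------------------------------------------
# feature-space generation
# ---------------------------------------------------------------------------

def group_boxes(cfg: SyntheticConfig, tree=None) -> dict:
    """Per-group, per-feature sampling intervals consistent with each
    group's root-to-leaf branch conditions, shrunk inward by
    ``margin_frac`` of the feature's plausible span."""
    tree = tree if tree is not None else reference_tree()
    paths = leaf_paths(tree)
    boxes: dict = {}
    for group in cfg.n_per_group:
        if group not in paths:
            raise SyntheticError(f"group {group!r} has no leaf in the tree")
        box = {}
        for feat, (lo, hi) in FEATURE_RANGES.items():
            box[feat] = (float(lo), float(hi))
        for feat, (thr, direction) in paths[group].items():
            lo, hi = FEATURE_RANGES[feat]
            margin = cfg.margin_frac * (hi - lo)
            if direction == "L":
                box[feat] = (float(lo), float(thr) - margin)
            else:
                box[feat] = (float(thr) + margin, float(hi))
        if cfg.feature_boxes and group in cfg.feature_boxes:
            box.update({
                f: (float(a), float(b))
                for f, (a, b) in cfg.feature_boxes[group].items()
            })
        for feat, (blo, bhi) in box.items():
            if blo > bhi:
                raise SyntheticError(
                    f"infeasible box for group {group!r}, feature {feat!r}: "
                    f"[{blo:g}, {bhi:g}]"
                )
            if feat in paths[group]:
                thr, direction = paths[group][feat]
                ok = bhi <= thr if direction == "L" else blo > thr or (
                    cfg.margin_frac == 0 and blo >= thr)
                if not ok:
                    raise SyntheticError(
                        f"box for group {group!r}, feature {feat!r} violates "
                        f"the path condition at threshold {thr:g}"
                    )
        boxes[group] = box
    return boxes


def _sample_feature(rng, feat, lo, hi):
    if feat in _INT_FEATURES:
        ilo, ihi = math.ceil(lo), math.floor(hi)
        if ilo > ihi:
            raise SyntheticError(
                f"integer feature {feat!r} has no admissible value in "
                f"[{lo:g}, {hi:g}]"
            )
        return float(rng.integers(ilo, ihi + 1))
    return float(rng.uniform(lo, hi))


def simulate_feature_table(cfg: SyntheticConfig, tree=None) -> pd.DataFrame:
    """Sample a labeled feature table from the per-group boxes.

    Returns a DataFrame with columns ``id``, ``label``, ``group`` and
    the 26 feature columns.  Complete records route (by construction)
    to their designated reference-tree group; ``n_missing_records``
    additional authentic first/last-exon mimics carry missing values on
    alternating splice-site sides and ``group`` NA.
    """
    rng = np.random.default_rng(cfg.seed)
    boxes = group_boxes(cfg, tree)
    rows = []
    for group in sorted(cfg.n_per_group):
        box = boxes[group]
        klass = "authentic" if group.isupper() else "cryptic"
        for i in range(cfg.n_per_group[group]):
            row = {"id": f"{group}_{i + 1:02d}", "label": klass, "group": group}
            for feat in FEATURE_NAMES:
                lo, hi = box[feat]
                row[feat] = _sample_feature(rng, feat, lo, hi)
            rows.append(row)

    from .features import ACCEPTOR_SIDE_FEATURES, DONOR_SIDE_FEATURES
    sides = (("first_exon_mimic", ACCEPTOR_SIDE_FEATURES),
             ("last_exon_mimic", DONOR_SIDE_FEATURES))
    box = boxes.get("C") or next(iter(boxes.values()))
    for j in range(cfg.n_missing_records):
        name, blank = sides[j % 2]
        row = {"id": f"{name}_{j // 2 + 1}" if j >= 2 else name,
               "label": "authentic", "group": np.nan}
        for feat in FEATURE_NAMES:
            lo, hi = box[feat]
            row[feat] = (np.nan if feat in blank
                         else _sample_feature(rng, feat, lo, hi))
        rows.append(row)

    return pd.DataFrame(
        rows, columns=list(META_COLUMNS) + ["group"] + list(FEATURE_NAMES))


# ---------------------------------------------------------------------------
# sequence-space generation
# ---------------------------------------------------------------------------

def _random_seq(rng, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _consensus(matrix) -> str:
    return "".join(max("ACGT", key=row.__getitem__) for row in matrix.values)


def _plant(rng, seq: list, kmers, count: int, occupied: set) -> None:
    if count == 0:
        return
    pool = sorted(kmers)
    tries = 0
    placed = 0
    while placed < count:
        tries += 1
        if tries > 10000:
            raise SyntheticError("could not place planted k-mers")
        km = pool[rng.integers(len(pool))]
        start = int(rng.integers(0, len(seq) - len(km) + 1))
        span = set(range(start, start + len(km)))
        if span & occupied:
            continue
        seq[start:start + len(km)] = list(km)
        occupied |= span
        placed += 1


def simulate_exon_records(cfg: SyntheticConfig,
                          bundle: Optional[ResourceBundle] = None) -> list:
    """Generate :class:`ExonRecord` sequences.

    Authentic records receive consensus-matched donor/acceptor windows
    and planted enhancer hexamers; cryptic records keep only the GT/AG
    splice dinucleotides (otherwise degenerate sites) and carry planted
    silencer hexamers.  The first/last ``n_missing_records`` mimics have
    one flank blanked.  Deterministic per seed.
    """
    bundle = bundle or load_resources()
    rng = np.random.default_rng([cfg.seed, 1])
    n_auth = sum(n for g, n in cfg.n_per_group.items() if g.isupper())
    n_cry = sum(n for g, n in cfg.n_per_group.items() if g.islower())
    n_auth += cfg.n_missing_records  # the excluded first/last exons

    donor_cons = _consensus(bundle.matrices["MaxEnt-lite-donor"])
    acceptor_cons = _consensus(bundle.matrices["MaxEnt-lite-acceptor"])
    ese = bundle.kmer_sets["RESCUE-ESE"].kmers
    ess = bundle.kmer_sets["FAS-ESS"].kmers

    records = []
    plan = [("authentic", i) for i in range(n_auth)]
    plan += [("cryptic", i) for i in range(n_cry)]
    for label, i in plan:
        length = int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
        planted = cfg.planted[label]
        need = 6 * (planted["ese"] + planted["ess"]) + 26
        if need > length:
            raise SyntheticError(
                f"exon length {length} cannot hold {planted} planted k-mers"
            )
        exon = list(_random_seq(rng, length, cfg.exon_gc))
        up = list(_random_seq(rng, cfg.flank_len, cfg.flank_gc))
        down = list(_random_seq(rng, cfg.flank_len, cfg.flank_gc))
        if label == "authentic":
            # consensus splice sites: 3 exonic + 6 intronic (donor),
            # 20 intronic + 3 exonic (acceptor)
            exon[-3:] = list(donor_cons[:3])
            down[:6] = list(donor_cons[3:])
            up[-20:] = list(acceptor_cons[:20])
            exon[:3] = list(acceptor_cons[20:])
        else:
            down[:2] = ["G", "T"]
            up[-2:] = ["A", "G"]
        occupied = set(range(0, 3)) | set(range(length - 3, length))
        _plant(rng, exon, ese, planted["ese"], occupied)
        _plant(rng, exon, ess, planted["ess"], occupied)
        rec_id = f"ex{i + 1:03d}" if label == "authentic" else f"crx{i + 1:02d}"
        records.append(ExonRecord(
            id=rec_id, label=label, exon_seq="".join(exon),
            up_flank="".join(up), down_flank="".join(down),
        ))

    # first/last-exon mimics: blank one flank each, alternating
    auth_idx = [k for k, r in enumerate(records) if r.label == "authentic"]
    for j in range(cfg.n_missing_records):
        k = auth_idx[j // 2] if j % 2 == 0 else auth_idx[-(j // 2 + 1)]
        r = records[k]
        records[k] = ExonRecord(
            id=r.id, label=r.label, exon_seq=r.exon_seq,
            up_flank="" if j % 2 == 0 else r.up_flank,
            down_flank=r.down_flank if j % 2 == 0 else "",
        )
    return records


# ---------------------------------------------------------------------------
# induction stress benchmark
# ---------------------------------------------------------------------------

def make_induction_benchmark(cfg: SyntheticConfig, overlap: float = 0.0):
    """Two-class table over three features with controlled box overlap.

    Authentic vectors are uniform in ``[0, 1]^3`` and cryptic vectors in
    ``[1 - overlap, 2 - overlap]^3``, so ``overlap = 0`` gives disjoint
    class boxes.  Returns ``(df, expected_accuracy_bound)`` where the
    bound (percent) is 100 unless identical vectors carry different
    classes, in which case it is the best achievable resubstitution
    accuracy.
    """
    if not 0 <= overlap < 1:
        raise SyntheticError("overlap must be in [0, 1)")
    rng = np.random.default_rng([cfg.seed, 2])
    n_auth = sum(n for g, n in cfg.n_per_group.items() if g.isupper())
    n_cry = sum(n for g, n in cfg.n_per_group.items() if g.islower())
    feats = ["f1", "f2", "f3"]
    rows = []
    for i in range(n_auth):
        rows.append({"id": f"auth_{i}", "label": "authentic",
                     **dict(zip(feats, rng.uniform(0, 1, 3)))})
    for i in range(n_cry):
        rows.append({"id": f"cry_{i}", "label": "cryptic",
                     **dict(zip(feats, rng.uniform(1 - overlap, 2 - overlap, 3)))})
    df = pd.DataFrame(rows)
    dup = df.groupby(feats)["label"].agg(["count", "nunique"])
    contradictions = int(
        (dup.loc[dup["nunique"] > 1, "count"] - 1).clip(lower=1).sum()
    ) if (dup["nunique"] > 1).any() else 0
    bound = 100.0 * (len(df) - contradictions) / len(df)
    return df, bound
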