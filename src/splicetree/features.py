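"""The 26 splicing-regulatory feature indexes.

For each exon the pipeline computes six splice-site strength scores
(Shapiro-matrix, log-odds/maximum-entropy-style, and information-content
scores, each at the donor and acceptor site), the free energy of U1 snRNA
binding at the donor site, four enhancer/silencer k-mer densities, five
SR-protein binding-site counts and their densities, the predicted
secondary-structure free energy and GC content of a 140-nt window around
each splice site, and the exon size.  Densities are per 100 nt of exon:
``density = 100 * count / length`` exactly.

Missing data are explicit: an exon lacking a flank (a first or last exon)
yields ``None`` for every feature on that side, serialized as ``NA``.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .records import ExonRecord, cut_windows
from .resources import (
    DuplexParams,
    KmerMotifSet,
    LookupTable,
    ResourceBundle,
    ScoringMatrix,
)

#: the 26 feature symbols, in canonical serialization order
FEATURE_NAMES = (
    "SH5'ss", "SH3'ss",
    "ME5'ss", "ME3'ss",
    "Ri5'ss", "Ri3'ss",
    "FE",
    "RESE-D", "PESE-D", "FESS-D", "PESS-D",
    "SF2/ASF-N", "SF2/ASF(IgM,BRCA1)-N", "SRp40-N", "SC35-N", "SRp55-N",
    "SF2/ASF-D", "SF2/ASF(IgM,BRCA1)-D", "SC35-D", "SRp40-D", "SRp55-D",
    "RSS5'ss", "RSS3'ss",
    "GC5'ss", "GC3'ss",
    "SIZE",
)

#: features undefined for a last exon (no downstream intron)
DONOR_SIDE_FEATURES = ("SH5'ss", "ME5'ss", "Ri5'ss", "FE", "RSS5'ss", "GC5'ss")
#: features undefined for a first exon (no upstream intron)
ACCEPTOR_SIDE_FEATURES = ("SH3'ss", "ME3'ss", "Ri3'ss", "RSS3'ss", "GC3'ss")

_RI_FLOOR = -20.0  # bits assigned to a base never seen at an alignment position


@dataclass
class FeatureVector:
    """The 26 named index values for one exon; ``None`` marks missing."""

    values: dict
    truncated: frozenset = frozenset()
    flags: tuple = ()

    def __post_init__(self):
        unknown = set(self.values) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names {sorted(unknown)}")
        for name in FEATURE_NAMES:
            self.values.setdefault(name, None)

    def __getitem__(self, name: str):
        return self.values[name]

    def missing_fields(self) -> tuple:
        return tuple(n for n in FEATURE_NAMES if self.values[n] is None)

    def is_complete(self) -> bool:
        return not self.missing_fields()


# ---------------------------------------------------------------------------
# splice-site strength scores
# ---------------------------------------------------------------------------

def shapiro_score(window: str, matrix: ScoringMatrix) -> Optional[float]:
    """Shapiro-style splice-site score normalised to [0, 1].

    ``(sum(f) - min) / (max - min)`` over the matched per-position base
    frequencies, where min/max are the least/most attainable sums of the
    matrix; the consensus window scores 1, the anti-consensus 0.
    """
    if len(window) != matrix.width:
        raise ValueError(
            f"window length {len(window)} != matrix width {matrix.width}"
        )
    if "N" in window:
        return None
    total = sum(row[b] for row, b in zip(matrix.values, window))
    lo, hi = matrix.min_score(), matrix.max_score()
    return (total - lo) / (hi - lo)


def logodds_splice_score(window: str, model) -> Optional[float]:
    """Splice-site strength as a sum of per-position log2-odds.

    ``model`` is either a positional log-odds :class:`ScoringMatrix`
    (the bundled stand-in for the maximum-entropy score) or a verbatim
    :class:`LookupTable` of canonical scores, returned bit-exactly.
    """
    if "N" in window:
        return None
    if isinstance(model, LookupTable):
        if len(window) != model.width:
            raise ValueError(
                f"window length {len(window)} != table width {model.width}"
            )
        try:
            return model.scores[window]
        except KeyError:
            raise KeyError(f"window {window!r} absent from lookup table {model.name}")
    if len(window) != model.width:
        raise ValueError(
            f"window length {len(window)} != matrix width {model.width}"
        )
    return sum(row[b] for row, b in zip(model.values, window))


@lru_cache(maxsize=8)
def build_ri_matrix(alignment: tuple) -> tuple:
    """Per-position individual-information weights from a splice-site
    alignment: ``log2(f_base / 0.25)`` per cell, with never-observed bases
    floored at -20 bits."""
    n = len(alignment)
    width = len(alignment[0])
    rows = []
    for pos in range(width):
        counts = {b: 0 for b in "ACGT"}
        for seq in alignment:
            counts[seq[pos]] += 1
        rows.append({
            b: (math.log2(c / n / 0.25) if c else _RI_FLOOR)
            for b, c in counts.items()
        })
    return tuple(rows)


def ri_score(window: str, alignment: tuple) -> Optional[float]:
    """Individual information Ri (bits) of a window against an alignment."""
    riw = build_ri_matrix(tuple(alignment))
    if len(window) != len(riw):
        raise ValueError(
            f"window length {len(window)} != alignment width {len(riw)}"
        )
    if "N" in window:
        return None
    return sum(row[b] for row, b in zip(riw, window))


# ---------------------------------------------------------------------------
# U1 snRNA duplex free energy
# ---------------------------------------------------------------------------

_RNA_PAIRS = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def _stack_energy(x1, y1, x2, y2, params: DuplexParams) -> float:
    # 5'x1x2 3' (transcript) stacked on 3'y1y2 5' (U1 tail)
    if (x1, y1) in _WC and (x2, y2) in _WC:
        return params.stacks[f"{x1}{x2}/{y1}{y2}"]
    return params.wobble_stack


def u1_duplex_energy(donor9: str, params: DuplexParams) -> float:
    """Free energy (kcal/mol) of the best ungapped antiparallel duplex
    between the transcript of the 9-nt donor window and the U1 snRNA
    5'-terminal tail.

    Every alignment register is scanned; within a register, each
    contiguous run of >=2 Watson-Crick or G.U pairs is scored as
    ``init_penalty + sum of nearest-neighbor stacks`` and the minimum
    over all runs and registers is returned.  With no pairable run of
    length >=2, or none more stable than the unbound state, the energy
    is 0 (no duplex forms).
    """
    a = donor9.replace("T", "U")
    if "N" in a:
        return 0.0
    c = params.u1_tail[::-1]  # U1 tail read 3' -> 5'
    best = None
    for shift in range(-(len(a) - 1), len(c)):
        run = []
        positions = list(range(len(a))) + [None]  # sentinel flushes last run
        for k in positions:
            partner = k + shift if k is not None else None
            if (
                k is not None
                and 0 <= partner < len(c)
                and (a[k], c[partner]) in _RNA_PAIRS
            ):
                run.append((a[k], c[partner]))
                continue
            if len(run) >= 2:
                e = params.init_penalty + sum(
                    _stack_energy(run[t][0], run[t][1],
                                  run[t + 1][0], run[t + 1][1], params)
                    for t in range(len(run) - 1)
                )
                if best is None or e < best:
                    best = e
            run = []
    return best if best is not None and best < 0 else 0.0


# ---------------------------------------------------------------------------
# exonic motif scanners
# ---------------------------------------------------------------------------

def kmer_density(exon_seq: str, s: KmerMotifSet) -> tuple:
    """Count k-mer motif starts in the exon (overlaps counted) and the
    per-100-nt density ``100 * count / exon length``.

    An exon shorter than ``k`` yields (0, 0.0); the caller flags it.
    """
    n, k = len(exon_seq), s.k
    if n < k:
        return 0, 0.0
    count = sum(1 for i in range(n - k + 1) if exon_seq[i:i + k] in s.kmers)
    return count, 100.0 * count / n


def pwm_hits(exon_seq: str, m: ScoringMatrix) -> tuple:
    """Count exon windows scoring at or above the matrix threshold, and
    the per-100-nt density (overlapping windows all counted)."""
    if m.threshold is None:
        raise ValueError(f"matrix {m.name} has no calling threshold")
    n, w = len(exon_seq), m.width
    if n < w:
        return 0, 0.0
    count = 0
    for i in range(n - w + 1):
        window = exon_seq[i:i + w]
        if "N" in window:
            continue
        if sum(row[b] for row, b in zip(m.values, window)) >= m.threshold:
            count += 1
    return count, 100.0 * count / n


# ---------------------------------------------------------------------------
# secondary structure and GC content
# ---------------------------------------------------------------------------

#: simplified per-pair energies (kcal/mol) for the internal folding model
PAIR_ENERGIES = {"GC": -3.0, "CG": -3.0, "AT": -2.0, "TA": -2.0,
                 "GT": -1.0, "TG": -1.0}
_MIN_LOOP = 3
_BIG = 1e9


def _internal_fold_energy(seq: str) -> float:
    """Energy-weighted Nussinov dynamic program (simplified model):
    maximise the total stability of nested base pairs under per-pair
    energies with a minimum hairpin loop of 3 nt."""
    n = len(seq)
    if n < _MIN_LOOP + 2:
        return 0.0
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    idx = code[enc]
    pe = np.full((5, 5), _BIG)
    bases = "ACGT"
    for pair, e in PAIR_ENERGIES.items():
        pe[bases.index(pair[0]), bases.index(pair[1])] = e

    E = np.zeros((n, n))
    for span in range(_MIN_LOOP + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = np.minimum(E[i + 1, j], E[i, j - 1])
        best = np.minimum(best, E[i + 1, j - 1] + pe[idx[i], idx[j]])
        for t in range(1, span):
            best = np.minimum(best, E[i, i + t] + E[i + t + 1, j])
        E[i, j] = best
    return float(E[0, n - 1])


def _rnafold_energy(seq: str) -> float:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError(
            "external folding backend requested but RNAfold is not on PATH; "
            "use backend='internal'"
        )
    out = subprocess.run(
        [exe, "--noPS"], input=seq.replace("T", "U") + "\n",
        capture_output=True, text=True, check=True,
    ).stdout
    last = out.strip().splitlines()[-1]
    return float(last[last.rindex("(") + 1:last.rindex(")")])


def structure_energy(win: str, backend: str = "internal") -> float:
    """Minimum free energy (kcal/mol) of the predicted secondary structure
    of a splice-site window.

    The internal backend is a documented simplified model (energy-weighted
    base-pair maximisation); the external backend delegates to an
    installed RNAfold."""
    if backend == "internal":
        return _internal_fold_energy(win)
    if backend == "external":
        return _rnafold_energy(win)
    raise ValueError(f"unknown folding backend {backend!r}")


def gc_window(win: str) -> float:
    """GC percentage of a window: ``100 * (#G + #C) / length``."""
    if not win:
        raise ValueError("empty window")
    return 100.0 * (win.count("G") + win.count("C")) / len(win)


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def extract_features(
    rec: ExonRecord,
    bundle: ResourceBundle,
    backend: str = "internal",
    ess_set: str = "FAS-ESS",
) -> FeatureVector:
    """Compute all 26 indexes for one exon record.

    Splice-site-dependent indexes on a side with an absent or too-short
    flank come back missing; 140-nt windows with a short *exonic* side
    are computed on the truncated window and flagged.
    """
    w = cut_windows(rec)
    exon = rec.exon_seq
    mx = bundle.matrices
    v: dict = {}
    flags = []

    def site(window, fn, *args):
        return fn(window, *args) if window is not None else None

    v["SH5'ss"] = site(w.donor_shapiro, shapiro_score, mx["Shapiro-donor"])
    v["SH3'ss"] = site(w.acceptor_shapiro, shapiro_score, mx["Shapiro-acceptor"])
    v["ME5'ss"] = site(
        w.donor9, logodds_splice_score,
        bundle.lookups.get("donor", mx["MaxEnt-lite-donor"]),
    )
    v["ME3'ss"] = site(
        w.acceptor23, logodds_splice_score,
        bundle.lookups.get("acceptor", mx["MaxEnt-lite-acceptor"]),
    )
    v["Ri5'ss"] = site(w.donor9, ri_score, bundle.alignments["donor"])
    v["Ri3'ss"] = site(w.acceptor23, ri_score, bundle.alignments["acceptor"])
    v["FE"] = site(w.donor9, u1_duplex_energy, bundle.duplex)

    for feat, set_name in [("RESE-D", "RESCUE-ESE"), ("PESE-D", "PESE"),
                           ("FESS-D", ess_set), ("PESS-D", "PESS")]:
        kset = bundle.kmer_sets[set_name]
        count, density = kmer_density(exon, kset)
        if len(exon) < kset.k:
            flags.append(f"{feat}: exon shorter than k={kset.k}")
        v[feat] = density

    for sr, nf, df in [
        ("SF2/ASF", "SF2/ASF-N", "SF2/ASF-D"),
        ("SF2/ASF(IgM,BRCA1)", "SF2/ASF(IgM,BRCA1)-N", "SF2/ASF(IgM,BRCA1)-D"),
        ("SRp40", "SRp40-N", "SRp40-D"),
        ("SC35", "SC35-N", "SC35-D"),
        ("SRp55", "SRp55-N", "SRp55-D"),
    ]:
        m = mx[sr]
        count, density = pwm_hits(exon, m)
        if len(exon) < m.width:
            flags.append(f"{nf}: exon shorter than matrix width {m.width}")
        v[nf], v[df] = count, density

    v["RSS5'ss"] = site(w.win5, structure_energy, backend)
    v["RSS3'ss"] = site(w.win3, structure_energy, backend)
    v["GC5'ss"] = site(w.win5, gc_window)
    v["GC3'ss"] = site(w.win3, gc_window)
    v["SIZE"] = float(len(exon))

    truncated = set()
    if w.win5_truncated:
        truncated.update({"RSS5'ss", "GC5'ss"})
    if w.win3_truncated:
        truncated.update({"RSS3'ss", "GC3'ss"})
    return FeatureVector(values=v, truncated=frozenset(truncated),
                         flags=tuple(flags))
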