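"""Loading and validation of the bundled scoring resources.

Every scorer in :mod:`splicetree.features` is parameterised by data, never
by hard-coded motifs: k-mer enhancer/silencer sets, SR-protein weight
matrices with calling thresholds, splice-site base-frequency and log-odds
matrices, splice-site alignments for the information-content score,
RNA/RNA duplex nearest-neighbor parameters, and the reference decision
tree.  The default bundle ships with the package; files whose name carries
a ``synthetic`` tag are deterministic stand-ins generated by
``scripts/build_synthetic_resources.py`` and mirror only the *shape* of
the corresponding published resources.  A user-supplied resource
directory can override any bundled file by name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Optional

log = logging.getLogger(__name__)

BASES = "ACGT"


class ResourceError(ValueError):
    """Raised for missing, malformed, or checksum-invalid resource files."""


@dataclass(frozen=True)
class KmerMotifSet:
    """A set of equal-length exonic splicing enhancer/silencer k-mers."""

    name: str
    k: int
    kmers: frozenset[str]
    source: str = ""

    def __post_init__(self):
        if not self.kmers:
            raise ResourceError(f"{self.name}: empty k-mer set")
        for km in self.kmers:
            if len(km) != self.k or set(km) - set(BASES):
                raise ResourceError(f"{self.name}: invalid k-mer {km!r}")


@dataclass(frozen=True)
class ScoringMatrix:
    """A per-position, per-base scoring table.

    ``kind`` distinguishes how the values are interpreted:

    - ``pwm`` — additive weights with a motif-calling ``threshold``
      (SR-protein matrices);
    - ``base-frequency-percent`` — Shapiro-style base frequencies,
      normalised to [0, 1] at scoring time;
    - ``positional-logodds`` — per-position log2-odds summed into a
      splice-site strength score.
    """

    name: str
    kind: str
    values: tuple[dict, ...]  # one {base: score} per position
    threshold: Optional[float] = None
    source: str = ""

    @property
    def width(self) -> int:
        return len(self.values)

    def max_score(self) -> float:
        return sum(max(row.values()) for row in self.values)

    def min_score(self) -> float:
        return sum(min(row.values()) for row in self.values)


@dataclass(frozen=True)
class DuplexParams:
    """Nearest-neighbor stack energies and the U1 snRNA 5'-terminal tail."""

    u1_tail: str
    init_penalty: float
    stacks: dict
    wobble_stack: float

    def __post_init__(self):
        if len(self.u1_tail) < 9:
            raise ResourceError("u1_tail must be at least 9 nt")
        for k, v in self.stacks.items():
            if not isinstance(v, (int, float)) or v != v:
                raise ResourceError(f"non-finite stack energy for {k}")


@dataclass(frozen=True)
class LookupTable:
    """Verbatim sequence -> score table (e.g. canonical maximum-entropy
    scores supplied by the user); returned scores bypass any model."""

    name: str
    width: int
    scores: dict


@dataclass
class ResourceBundle:
    kmer_sets: dict = field(default_factory=dict)
    matrices: dict = field(default_factory=dict)
    alignments: dict = field(default_factory=dict)
    duplex: Optional[DuplexParams] = None
    reference_tree: Optional[dict] = None
    signatures_path: Optional[Path] = None
    lookups: dict = field(default_factory=dict)
    sources: dict = field(default_factory=dict)


def default_resource_dir() -> Path:
    return Path(importlib_resources.files("splicetree") / "data")


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> ScoringMatrix:
    meta, rows = {}, []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if fields[0] == "pos":
                continue
            if len(fields) != 5:
                raise ResourceError(
                    f"{path}:{line_no}: matrix row needs pos + 4 base entries, "
                    f"got {len(fields)} fields"
                )
            try:
                rows.append(dict(zip(BASES, map(float, fields[1:]))))
            except ValueError as exc:
                raise ResourceError(f"{path}:{line_no}: non-numeric entry") from exc
    if not rows:
        raise ResourceError(f"{path}: no matrix rows")
    width = meta.get("width")
    if width is not None and int(width) != len(rows):
        raise ResourceError(
            f"{path}: declared width {width} != {len(rows)} rows"
        )
    thr = meta.get("threshold")
    return ScoringMatrix(
        name=meta.get("name", path.stem),
        kind=meta.get("kind", "pwm"),
        values=tuple(rows),
        threshold=float(thr) if thr is not None else None,
        source=str(path),
    )


def _read_kmers(path: Path, name: str) -> KmerMotifSet:
    kmers = [l.strip().upper() for l in path.read_text().splitlines() if l.strip()]
    lengths = {len(k) for k in kmers}
    if len(lengths) != 1:
        raise ResourceError(f"{path}: mixed k-mer lengths {sorted(lengths)}")
    return KmerMotifSet(name=name, k=lengths.pop(), kmers=frozenset(kmers),
                        source=str(path))


def _read_alignment(path: Path) -> tuple[str, ...]:
    seqs = tuple(
        l.strip().upper() for l in path.read_text().splitlines() if l.strip()
    )
    if not seqs:
        raise ResourceError(f"{path}: empty alignment")
    if len({len(s) for s in seqs}) != 1:
        raise ResourceError(f"{path}: unequal alignment row lengths")
    return seqs


def read_lookup_table(path, name: str = "maxent-lookup") -> LookupTable:
    """Read a user-supplied verbatim ``sequence<TAB>score`` table."""
    scores = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                seq, score = line.split("\t")
                scores[seq.upper()] = float(score)
            except ValueError as exc:
                raise ResourceError(
                    f"{path}:{line_no}: expected 'sequence<TAB>score'"
                ) from exc
    if not scores:
        raise ResourceError(f"{path}: empty lookup table")
    widths = {len(s) for s in scores}
    if len(widths) != 1:
        raise ResourceError(f"{path}: mixed sequence lengths {sorted(widths)}")
    return LookupTable(name=name, width=widths.pop(), scores=scores)


# ---------------------------------------------------------------------------
# bundle loading
# ---------------------------------------------------------------------------

_KMER_FILES = {
    "RESCUE-ESE": "rescue_ese_hexamers.synthetic.txt",
    "FAS-ESS": "fas_ess_hex3.synthetic.txt",
    "FAS-ESS-hex2": "fas_ess_hex2.synthetic.txt",
    "PESE": "pese_octamers.synthetic.txt",
    "PESS": "pess_octamers.synthetic.txt",
}

_MATRIX_FILES = (
    "shapiro_donor.synthetic.tsv",
    "shapiro_acceptor.synthetic.tsv",
    "maxent_lite_donor.synthetic.tsv",
    "maxent_lite_acceptor.synthetic.tsv",
    "sf2_asf.synthetic.tsv",
    "sf2_asf_igm_brca1.synthetic.tsv",
    "sc35.synthetic.tsv",
    "srp40.synthetic.tsv",
    "srp55.synthetic.tsv",
)

_ALIGNMENT_FILES = {
    "donor": "donor_sites.synthetic.txt",
    "acceptor": "acceptor_sites.synthetic.txt",
}


def _verify_checksums(directory: Path) -> None:
    manifest_path = directory / "MANIFEST.json"
    if not manifest_path.exists():
        raise ResourceError(f"missing manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    for fname, meta in manifest.items():
        p = directory / fname
        if not p.exists():
            raise ResourceError(f"resource file {fname} listed in manifest is missing")
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        if digest != meta["sha256"]:
            raise ResourceError(f"checksum mismatch for {fname}")


def load_resources(resource_dir=None, overrides_dir=None) -> ResourceBundle:
    """Load and validate the full resource bundle.

    ``resource_dir`` defaults to the packaged data directory; its manifest
    checksums are verified.  ``overrides_dir`` may supply replacement
    files by name (overrides are logged, not checksum-checked, so a user
    can swap in e.g. the canonical maximum-entropy tables or an
    alternative SR matrix).
    """
    directory = Path(resource_dir) if resource_dir else default_resource_dir()
    if resource_dir is None or (directory / "MANIFEST.json").exists():
        _verify_checksums(directory)

    def locate(fname: str) -> Path:
        if overrides_dir is not None:
            cand = Path(overrides_dir) / fname
            if cand.exists():
                digest = hashlib.sha256(cand.read_bytes()).hexdigest()[:12]
                log.info("resource %s overridden by %s (sha256 %s...)",
                         fname, cand, digest)
                return cand
        p = directory / fname
        if not p.exists():
            raise ResourceError(f"missing resource file {p}")
        return p

    bundle = ResourceBundle()
    for name, fname in _KMER_FILES.items():
        bundle.kmer_sets[name] = _read_kmers(locate(fname), name)
    for fname in _MATRIX_FILES:
        m = _read_matrix(locate(fname))
        bundle.matrices[m.name] = m
    for name, fname in _ALIGNMENT_FILES.items():
        bundle.alignments[name] = _read_alignment(locate(fname))
    dp = json.loads(locate("duplex_params.json").read_text())
    bundle.duplex = DuplexParams(
        u1_tail=dp["u1_tail"],
        init_penalty=dp["init_penalty"],
        stacks=dp["stacks"],
        wobble_stack=dp["wobble_stack"],
    )
    bundle.reference_tree = json.loads(locate("reference_tree.json").read_text())
    bundle.signatures_path = locate("group_signatures.tsv")
    for res in list(bundle.kmer_sets.values()) + list(bundle.matrices.values()):
        bundle.sources[res.name] = res.source
    return bundle


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

def validate_kmer_set(name: str, kmers, k: int) -> list[str]:
    """Report duplicates, wrong-length and non-ACGT entries in a raw k-mer
    list; a clean set yields an empty report."""
    findings, seen = [], set()
    for km in kmers:
        if km in seen:
            findings.append(f"{name}: duplicate entry {km!r}")
        seen.add(km)
        if len(km) != k:
            findings.append(f"{name}: wrong-length entry {km!r} (expected k={k})")
        elif set(km) - set(BASES):
            findings.append(f"{name}: non-ACGT entry {km!r}")
    return findings
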