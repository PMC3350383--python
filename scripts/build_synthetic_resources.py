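"""Regenerate the bundled resource files under ``src/splicetree/data``.

Every motif set, frequency matrix, log-odds table and splice-site alignment
shipped with the package is a deterministic synthetic stand-in built by this
script (filenames carry a ``synthetic`` tag).  They reproduce the *shape* of
the published resources — purine-rich enhancer hexamers, U/G-rich silencer
k-mers, SR-protein weight matrices with their conventional calling
thresholds, canonical donor/acceptor consensus frequencies — without copying
any third-party table.  The reference decision tree and the group-signature
table are published results and are written verbatim, not synthesised.

Run from the repository root:

    python scripts/build_synthetic_resources.py
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parents[1] / "src" / "splicetree" / "data"
BASES = "ACGT"
SEED = 4251


# ---------------------------------------------------------------------------
# consensus base frequencies (percent) for the splice-site windows
# ---------------------------------------------------------------------------

DONOR_FREQ = [
    # -3 .. -1 exonic, +1 .. +6 intronic; consensus CAG|GTAAGT
    {"A": 33, "C": 37, "G": 18, "T": 12},
    {"A": 60, "C": 13, "G": 14, "T": 13},
    {"A": 8, "C": 4, "G": 81, "T": 7},
    {"A": 0, "C": 0, "G": 100, "T": 0},
    {"A": 0, "C": 2, "G": 0, "T": 98},
    {"A": 55, "C": 3, "G": 38, "T": 4},
    {"A": 71, "C": 8, "G": 12, "T": 9},
    {"A": 7, "C": 5, "G": 82, "T": 6},
    {"A": 17, "C": 18, "G": 20, "T": 45},
]

# -20 .. -1 intronic (polypyrimidine tract then the invariant AG), +1 .. +3 exonic
ACCEPTOR_FREQ = (
    [
        {"A": 10 + d, "C": 31, "G": 11 - d, "T": 48}
        for d in (0, 1, -1, 2, 0, -2, 1, 0, -1, 2, 0, 1, -2, 0, 1)
    ]
    + [
        {"A": 7, "C": 37, "G": 8, "T": 48},
        {"A": 24, "C": 29, "G": 21, "T": 26},
        {"A": 4, "C": 64, "G": 1, "T": 31},
        {"A": 100, "C": 0, "G": 0, "T": 0},
        {"A": 0, "C": 0, "G": 100, "T": 0},
        {"A": 28, "C": 14, "G": 47, "T": 11},
        {"A": 30, "C": 20, "G": 25, "T": 25},
        {"A": 26, "C": 24, "G": 27, "T": 23},
    ]
)

# Shapiro-style acceptor span: 12 intronic + 2 exonic positions
ACCEPTOR_SHAPIRO_FREQ = ACCEPTOR_FREQ[8:22]


def write_matrix(name, path, kind, freq=None, weights=None, threshold=None, note=""):
    lines = [f"# name: {name}", f"# kind: {kind}"]
    rows = freq if freq is not None else weights
    lines.append(f"# width: {len(rows)}")
    if threshold is not None:
        lines.append(f"# threshold: {threshold}")
    if note:
        lines.append(f"# note: {note}")
    lines.append("pos\tA\tC\tG\tT")
    for i, row in enumerate(rows, start=1):
        vals = "\t".join(
            str(row[b]) if isinstance(row[b], int) else f"{row[b]:.4f}" for b in BASES
        )
        lines.append(f"{i}\t{vals}")
    path.write_text("\n".join(lines) + "\n")


def logodds_rows(freq_rows, floor=0.005):
    out = []
    for row in freq_rows:
        out.append(
            {b: math.log2(max(row[b] / 100.0, floor) / 0.25) for b in BASES}
        )
    return out


def sample_kmers(rng, k, n, probs, exclude=frozenset()):
    seen, out = set(exclude), []
    while len(out) < n:
        kmer = "".join(rng.choice(list(BASES), size=k, p=probs))
        if kmer not in seen:
            seen.add(kmer)
            out.append(kmer)
    return sorted(out)


def sr_matrix(rng, consensus):
    rows = []
    for c in consensus:
        second = rng.choice([b for b in BASES if b != c])
        row = {}
        for b in BASES:
            if b == c:
                row[b] = round(float(rng.uniform(1.05, 1.45)), 4)
            elif b == second:
                row[b] = round(float(rng.uniform(0.25, 0.70)), 4)
            else:
                row[b] = round(float(rng.uniform(-1.60, -0.80)), 4)
        rows.append(row)
    return rows


def sample_alignment(rng, freq_rows, n):
    seqs = []
    for _ in range(n):
        seqs.append(
            "".join(
                rng.choice(list(BASES), p=[row[b] / 100.0 for b in BASES])
                for row in freq_rows
            )
        )
    return seqs


REFERENCE_TREE = {
    "feature": "ME3'ss",
    "threshold": 1.39,
    "yes": {"class": "cryptic", "group": "a", "n": 4},
    "no": {
        "feature": "SF2/ASF-D",
        "threshold": 10.53,
        "no": {"class": "authentic", "group": "A", "n": 30},
        "yes": {
            "feature": "ME5'ss",
            "threshold": 5.58,
            "yes": {
                "feature": "FE",
                "threshold": -2.6,
                "yes": {"class": "cryptic", "group": "b", "n": 5},
                "no": {"class": "authentic", "group": "B", "n": 1},
            },
            "no": {
                "feature": "FESS-D",
                "threshold": 4.45,
                "yes": {
                    "feature": "GC5'ss",
                    "threshold": 46.8,
                    "yes": {"class": "authentic", "group": "C", "n": 42},
                    "no": {
                        "feature": "SH3'ss",
                        "threshold": 0.79,
                        "yes": {"class": "cryptic", "group": "c", "n": 2},
                        "no": {"class": "authentic", "group": "E", "n": 2},
                    },
                },
                "no": {
                    "feature": "SIZE",
                    "threshold": 144,
                    "yes": {"class": "authentic", "group": "D", "n": 2},
                    "no": {"class": "cryptic", "group": "d", "n": 4},
                },
            },
        },
    },
}

SIGNATURES = """\
group	class	n	ME3'ss	SF2/ASF-D	ME5'ss	FE	FESS-D	GC5'ss	SH3'ss	SIZE
A	authentic	30	H	H	-	-	-	-	-	-
B	authentic	1	H	L	L	H	-	-	-	-
C	authentic	42	H	L	H	-	L	L	-	-
D	authentic	2	H	L	H	-	H	-	-	L
E	authentic	2	H	L	H	-	L	H	H	-
a	cryptic	4	L	-	-	-	-	-	-	-
b	cryptic	5	H	L	L	L	-	-	-	-
c	cryptic	2	H	L	H	-	L	H	L	-
d	cryptic	4	H	L	H	-	H	-	-	H
"""

# Watson-Crick nearest-neighbor stack free energies (kcal/mol, 37 C),
# 5'XY3' paired antiparallel to 3'ZW5'.  Turner-style values; wobble
# (G.U-containing) stacks are covered by a single compiled fallback.
WC_STACKS = {
    "AA/UU": -0.93, "UU/AA": -0.93,
    "AU/UA": -1.10, "UA/AU": -1.33,
    "CU/GA": -2.08, "AG/UC": -2.08,
    "CA/GU": -2.11, "UG/AC": -2.11,
    "GU/CA": -2.24, "AC/UG": -2.24,
    "GA/CU": -2.35, "UC/AG": -2.35,
    "CG/GC": -2.36, "GC/CG": -3.42,
    "GG/CC": -3.26, "CC/GG": -3.26,
}


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # --- splice-site matrices -------------------------------------------
    write_matrix(
        "Shapiro-donor", DATA / "shapiro_donor.synthetic.tsv",
        "base-frequency-percent", freq=DONOR_FREQ,
        note="synthetic consensus-frequency stand-in; 3 exonic + 6 intronic nt",
    )
    write_matrix(
        "Shapiro-acceptor", DATA / "shapiro_acceptor.synthetic.tsv",
        "base-frequency-percent", freq=ACCEPTOR_SHAPIRO_FREQ,
        note="synthetic consensus-frequency stand-in; 12 intronic + 2 exonic nt",
    )
    write_matrix(
        "MaxEnt-lite-donor", DATA / "maxent_lite_donor.synthetic.tsv",
        "positional-logodds", weights=logodds_rows(DONOR_FREQ),
        note="synthetic positional log2-odds stand-in for the maximum-entropy donor score",
    )
    write_matrix(
        "MaxEnt-lite-acceptor", DATA / "maxent_lite_acceptor.synthetic.tsv",
        "positional-logodds", weights=logodds_rows(ACCEPTOR_FREQ),
        note="synthetic positional log2-odds stand-in for the maximum-entropy acceptor score",
    )

    # --- SR-protein weight matrices (ESEfinder-style, synthetic weights,
    #     conventional v3.0 calling thresholds) ---------------------------
    for name, fname, consensus, thr in [
        ("SF2/ASF", "sf2_asf.synthetic.tsv", "CAGAAGA", 1.956),
        ("SF2/ASF(IgM,BRCA1)", "sf2_asf_igm_brca1.synthetic.tsv", "CTGAAGA", 1.867),
        ("SC35", "sc35.synthetic.tsv", "GGACTTCA", 2.383),
        ("SRp40", "srp40.synthetic.tsv", "ACAGGCA", 2.67),
        ("SRp55", "srp55.synthetic.tsv", "TCACGA", 2.676),
    ]:
        write_matrix(
            name, DATA / fname, "pwm", weights=sr_matrix(rng, consensus),
            threshold=thr, note="synthetic SR-protein weight-matrix stand-in",
        )

    # --- k-mer motif sets ------------------------------------------------
    ese_p = [0.40, 0.10, 0.40, 0.10]   # purine-rich enhancer flavour
    ess_p = [0.15, 0.15, 0.35, 0.35]   # U/G-rich silencer flavour
    rese = sample_kmers(rng, 6, 60, ese_p)
    hex3 = sample_kmers(rng, 6, 50, ess_p, exclude=set(rese))
    hex2 = sorted(hex3 + sample_kmers(rng, 6, 25, ess_p, exclude=set(rese) | set(hex3)))
    pese = sample_kmers(rng, 8, 80, ese_p)
    pess = sample_kmers(rng, 8, 80, ess_p, exclude=set(pese))
    for fname, kmers in [
        ("rescue_ese_hexamers.synthetic.txt", rese),
        ("fas_ess_hex3.synthetic.txt", hex3),
        ("fas_ess_hex2.synthetic.txt", hex2),
        ("pese_octamers.synthetic.txt", pese),
        ("pess_octamers.synthetic.txt", pess),
    ]:
        (DATA / fname).write_text("\n".join(kmers) + "\n")

    # --- splice-site alignments for the information-content score --------
    (DATA / "donor_sites.synthetic.txt").write_text(
        "\n".join(sample_alignment(rng, DONOR_FREQ, 150)) + "\n"
    )
    (DATA / "acceptor_sites.synthetic.txt").write_text(
        "\n".join(sample_alignment(rng, ACCEPTOR_FREQ, 150)) + "\n"
    )

    # --- duplex parameters ----------------------------------------------
    (DATA / "duplex_params.json").write_text(
        json.dumps(
            {
                "u1_tail": "AUACUUACCUGG",
                "init_penalty": 4.09,
                "wobble_stack": -1.0,
                "stacks": WC_STACKS,
            },
            indent=1,
        )
        + "\n"
    )

    # --- published reference tree and group signatures -------------------
    (DATA / "reference_tree.json").write_text(
        json.dumps(REFERENCE_TREE, indent=1) + "\n"
    )
    (DATA / "group_signatures.tsv").write_text(SIGNATURES)

    # --- manifest ---------------------------------------------------------
    manifest = {}
    for p in sorted(DATA.iterdir()):
        if p.name == "MANIFEST.json":
            continue
        manifest[p.name] = {
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            "synthetic": ".synthetic." in p.name,
        }
    (DATA / "MANIFEST.json").write_text(json.dumps(manifest, indent=1) + "\n")
    print(f"wrote {len(manifest) + 1} files to {DATA}")


if __name__ == "__main__":
    main()
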