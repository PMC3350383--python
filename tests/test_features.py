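"""Scorer unit tests, each [non-trivial] value checked against an
independent oracle: spreadsheet-style matrix sums, hand-counted
alignments, brute-force window scans, exhaustive duplex-register
enumeration and a recursive folding dynamic program."""

import math
from functools import lru_cache

import numpy as np
import pytest

from splicetree.features import (
    ACCEPTOR_SIDE_FEATURES,
    DONOR_SIDE_FEATURES,
    FEATURE_NAMES,
    PAIR_ENERGIES,
    extract_features,
    gc_window,
    kmer_density,
    logodds_splice_score,
    pwm_hits,
    ri_score,
    shapiro_score,
    structure_energy,
    u1_duplex_energy,
)
from splicetree.records import ExonRecord
from splicetree.resources import (
    DuplexParams,
    KmerMotifSet,
    LookupTable,
    ScoringMatrix,
    default_resource_dir,
)

RNG = np.random.default_rng(20)


def random_dna(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# Shapiro score
# ---------------------------------------------------------------------------

def test_shapiro_consensus_and_anticonsensus_hit_the_unit_bounds(bundle):
    m = bundle.matrices["Shapiro-donor"]
    cons = "".join(max("ACGT", key=row.__getitem__) for row in m.values)
    anti = "".join(min("ACGT", key=row.__getitem__) for row in m.values)
    assert shapiro_score(cons, m) == pytest.approx(1.0)
    assert shapiro_score(anti, m) == pytest.approx(0.0)


def test_shapiro_matches_manual_matrix_file_summation(bundle):
    # independent parse of the bundled matrix file, spreadsheet style
    rows = []
    for line in (default_resource_dir() / "shapiro_donor.synthetic.tsv") \
            .read_text().splitlines():
        if line and not line.startswith(("#", "pos")):
            _, a, c, g, t = line.split("\t")
            rows.append({"A": float(a), "C": float(c),
                         "G": float(g), "T": float(t)})
    window = "CAGGTAAGT"
    total = sum(r[b] for r, b in zip(rows, window))
    lo = sum(min(r.values()) for r in rows)
    hi = sum(max(r.values()) for r in rows)
    expected = (total - lo) / (hi - lo)
    assert shapiro_score(window, bundle.matrices["Shapiro-donor"]) == \
        pytest.approx(expected)


def test_shapiro_window_with_n_is_missing(bundle):
    assert shapiro_score("CAGGTANGT", bundle.matrices["Shapiro-donor"]) is None


# ---------------------------------------------------------------------------
# log-odds splice score
# ---------------------------------------------------------------------------

def test_logodds_is_zero_when_model_equals_background():
    uniform = ScoringMatrix(
        name="u", kind="positional-logodds",
        values=tuple({b: 0.0 for b in "ACGT"} for _ in range(9)),
    )
    assert logodds_splice_score("CAGGTAAGT", uniform) == pytest.approx(0.0)


def test_logodds_matches_brute_force_table_sum(bundle):
    m = bundle.matrices["MaxEnt-lite-donor"]
    window = "CAGGTAAGT"
    expected = sum(m.values[i][b] for i, b in enumerate(window))
    assert logodds_splice_score(window, m) == pytest.approx(expected)


def test_logodds_monotone_in_per_position_probability(bundle):
    m = bundle.matrices["MaxEnt-lite-donor"]
    rng = np.random.default_rng(5)
    for _ in range(50):
        w = list(random_dna(9, rng))
        pos = int(rng.integers(9))
        before = logodds_splice_score("".join(w), m)
        w[pos] = max("ACGT", key=m.values[pos].__getitem__)
        assert logodds_splice_score("".join(w), m) >= before - 1e-12


def test_canonical_lookup_table_is_returned_verbatim():
    table = LookupTable(name="ext", width=9, scores={"CAGGTAAGT": 11.08})
    assert logodds_splice_score("CAGGTAAGT", table) == 11.08


# ---------------------------------------------------------------------------
# information-content score
# ---------------------------------------------------------------------------

def test_ri_is_zero_on_a_uniform_alignment():
    aln = ("AA", "CC", "GG", "TT")
    assert ri_score("GT", aln) == pytest.approx(0.0)
    assert ri_score("CA", aln) == pytest.approx(0.0)


def test_ri_hand_counted_toy_alignment():
    aln = ("GT", "GT", "GA", "CT")
    # pos 1: G 3/4, pos 2: T 3/4 -> Ri("GT") = 2 * log2(0.75/0.25)
    assert ri_score("GT", aln) == pytest.approx(2 * math.log2(3))


def test_ri_consensus_attains_the_row_max_sum(bundle):
    from splicetree.features import build_ri_matrix

    aln = bundle.alignments["donor"]
    riw = build_ri_matrix(tuple(aln))
    cons = "".join(max("ACGT", key=row.__getitem__) for row in riw)
    assert ri_score(cons, aln) == pytest.approx(
        sum(max(row.values()) for row in riw))


# ---------------------------------------------------------------------------
# U1 duplex free energy
# ---------------------------------------------------------------------------

def _oracle_duplex(donor9: str, params: DuplexParams) -> float:
    """Exhaustive register enumeration, written independently."""
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
             ("G", "U"), ("U", "G")}
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    a = donor9.replace("T", "U")
    c = params.u1_tail[::-1]
    candidates = []
    for shift in range(-len(a) + 1, len(c)):
        k = 0
        while k < len(a):
            run = []
            while (k < len(a) and 0 <= k + shift < len(c)
                   and (a[k], c[k + shift]) in pairs):
                run.append((a[k], c[k + shift]))
                k += 1
            if len(run) >= 2:
                e = params.init_penalty
                for (x1, y1), (x2, y2) in zip(run, run[1:]):
                    if (x1, y1) in wc and (x2, y2) in wc:
                        e += params.stacks[f"{x1}{x2}/{y1}{y2}"]
                    else:
                        e += params.wobble_stack
                candidates.append(e)
            k += 1
    best = min(candidates, default=0.0)
    return best if best < 0 else 0.0


def test_duplex_perfect_complement_is_stable(bundle):
    # CAG|GUAAGU pairs the U1 tail 3'-GUCCAUUCA-5' over all 9 positions
    assert u1_duplex_energy("CAGGTAAGT", bundle.duplex) < 0


def test_duplex_no_pairable_register_gives_zero():
    params = DuplexParams(u1_tail="CGCGCGCGC", init_penalty=4.09,
                          stacks=bundle_stacks(), wobble_stack=-1.0)
    assert u1_duplex_energy("AAAAAAAAA", params) == 0.0


def bundle_stacks():
    from splicetree.resources import load_resources

    return load_resources().duplex.stacks


def test_duplex_matches_exhaustive_register_enumeration(bundle):
    rng = np.random.default_rng(8)
    windows = ["CAGGTAAGT", "AAGGTGAGT", "TTTGCAAAT"] + [
        random_dna(9, rng) for _ in range(40)
    ]
    for w in windows:
        assert u1_duplex_energy(w, bundle.duplex) == \
            pytest.approx(_oracle_duplex(w, bundle.duplex)), w


# ---------------------------------------------------------------------------
# k-mer and PWM scanners
# ---------------------------------------------------------------------------

def test_kmer_density_counts_overlapping_starts():
    s = KmerMotifSet(name="t", k=6, kmers=frozenset({"GAAGAA"}))
    count, density = kmer_density("GAAGAAGAA", s)
    assert count == 2
    assert density == pytest.approx(100.0 * 2 / 9)


def test_kmer_density_zero_and_short_exon():
    s = KmerMotifSet(name="t", k=6, kmers=frozenset({"GAAGAA"}))
    assert kmer_density("CCCCCCCC", s) == (0, 0.0)
    assert kmer_density("CCC", s) == (0, 0.0)


def test_density_identity_holds_for_every_scanner(bundle):
    rng = np.random.default_rng(9)
    exon = random_dna(100, rng)
    for s in bundle.kmer_sets.values():
        count, density = kmer_density(exon, s)
        assert density * len(exon) / 100.0 == pytest.approx(count)
    for m in bundle.matrices.values():
        if m.threshold is None:
            continue
        count, density = pwm_hits(exon, m)
        assert density * len(exon) / 100.0 == pytest.approx(count)


def test_pwm_hits_matches_brute_force_scan(bundle):
    m = bundle.matrices["SF2/ASF"]
    rng = np.random.default_rng(10)
    for _ in range(20):
        exon = random_dna(int(rng.integers(20, 80)), rng)
        expected = 0
        for i in range(len(exon) - m.width + 1):
            score = sum(m.values[j][exon[i + j]] for j in range(m.width))
            expected += score >= m.threshold
        count, density = pwm_hits(exon, m)
        assert count == expected
        assert density == pytest.approx(100.0 * expected / len(exon))


def test_pwm_all_windows_below_threshold():
    m = ScoringMatrix(name="t", kind="pwm", threshold=5.0,
                      values=tuple({b: 0.0 for b in "ACGT"} for _ in range(4)))
    assert pwm_hits("ACGTACGTACGT", m) == (0, 0.0)


# ---------------------------------------------------------------------------
# secondary structure and GC
# ---------------------------------------------------------------------------

def _oracle_fold(seq: str) -> float:
    @lru_cache(maxsize=None)
    def E(i, j):
        if j - i <= 3:
            return 0.0
        best = min(E(i + 1, j), E(i, j - 1))
        pe = PAIR_ENERGIES.get(seq[i] + seq[j])
        if pe is not None:
            best = min(best, E(i + 1, j - 1) + pe)
        for k in range(i + 1, j):
            best = min(best, E(i, k) + E(k + 1, j))
        return best

    return E(0, len(seq) - 1)


def test_fold_homopolymer_has_no_pairs():
    assert structure_energy("A" * 30) == 0.0


def test_fold_longer_stem_is_more_stable():
    e30 = structure_energy("G" * 30 + "A" * 80 + "C" * 30)
    e15 = structure_energy("G" * 15 + "A" * 80 + "C" * 15)
    assert e30 < 0 and e30 <= e15


def test_fold_matches_independent_dynamic_program():
    rng = np.random.default_rng(11)
    for _ in range(15):
        seq = random_dna(25, rng)
        assert structure_energy(seq) == pytest.approx(_oracle_fold(seq)), seq


def test_external_backend_requires_rnafold(monkeypatch):
    monkeypatch.setattr("shutil.which", lambda _: None)
    with pytest.raises(RuntimeError, match="internal"):
        structure_energy("ACGUACGU", backend="external")


@pytest.mark.parametrize(
    "win, expected",
    [("GC" * 10, 100.0), ("AT" * 10, 0.0), ("G" * 70 + "A" * 70, 50.0)],
)
def test_gc_window(win, expected):
    assert gc_window(win) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def test_internal_exon_yields_all_26_features(bundle):
    rng = np.random.default_rng(12)
    rec = ExonRecord(id="x", label="authentic", exon_seq=random_dna(120, rng),
                     up_flank=random_dna(80, rng), down_flank=random_dna(80, rng))
    fv = extract_features(rec, bundle)
    assert len(FEATURE_NAMES) == 26
    assert fv.is_complete()
    assert fv["SIZE"] == 120
    # count/density pairing is exact
    assert fv["SF2/ASF-D"] * 120 / 100.0 == pytest.approx(fv["SF2/ASF-N"])


def test_last_exon_misses_exactly_the_donor_side_features(bundle):
    rng = np.random.default_rng(13)
    rec = ExonRecord(id="x", label="authentic", exon_seq=random_dna(120, rng),
                     up_flank=random_dna(80, rng), down_flank="")
    fv = extract_features(rec, bundle)
    assert set(fv.missing_fields()) == set(DONOR_SIDE_FEATURES)


def test_first_exon_misses_exactly_the_acceptor_side_features(bundle):
    rng = np.random.default_rng(14)
    rec = ExonRecord(id="x", label="authentic", exon_seq=random_dna(120, rng),
                     up_flank="", down_flank=random_dna(80, rng))
    fv = extract_features(rec, bundle)
    assert set(fv.missing_fields()) == set(ACCEPTOR_SIDE_FEATURES)


def test_exon_size_is_the_nucleotide_count(bundle):
    rng = np.random.default_rng(15)
    rec = ExonRecord(id="11a", label="cryptic", exon_seq=random_dna(157, rng),
                     up_flank=random_dna(75, rng), down_flank=random_dna(75, rng))
    assert extract_features(rec, bundle)["SIZE"] == 157


def test_truncated_windows_are_flagged_not_missing(bundle):
    rng = np.random.default_rng(16)
    rec = ExonRecord(id="x", label="authentic", exon_seq=random_dna(50, rng),
                     up_flank=random_dna(80, rng), down_flank=random_dna(80, rng))
    fv = extract_features(rec, bundle)
    assert fv["GC5'ss"] is not None
    assert {"RSS5'ss", "GC5'ss", "RSS3'ss", "GC3'ss"} <= set(fv.truncated)
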