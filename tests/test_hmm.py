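"""Profile HMM: construction, HMMER2 format round-trips, Viterbi/forward
scoring against a path-enumeration oracle, calibration and
classification."""

import itertools
import math

import numpy as np
import pytest

from madascan import hmm
from madascan.records import AMINO_ACIDS, SequenceRecord

from conftest import random_protein


def test_build_consensus_is_best_scoring_word():
    """Model from 10 copies of MADA: MADA is the highest-scoring 4-mer
    among all 20^4 sequences (exhaustive scoring by the emission table)."""
    model = hmm.build_hmm(["MADA"] * 10)
    assert model.n_states == 4
    log_odds = np.log2(model.match_emissions) - np.log2(model.background)
    scores = {}
    for word in itertools.product(range(20), repeat=4):
        scores[word] = sum(log_odds[i, c] for i, c in enumerate(word))
    best = max(scores, key=scores.get)
    assert "".join(AMINO_ACIDS[c] for c in best) == "MADA"


def test_build_single_row_closed_form():
    """One row: emissions equal the (c + 1) / (1 + 20) Laplace formula."""
    model = hmm.build_hmm(["MK"])
    expected_hit = (1 + 1) / (1 + 20)
    expected_miss = 1 / (1 + 20)
    assert model.match_emissions[0, AMINO_ACIDS.index("M")] == pytest.approx(expected_hit)
    assert model.match_emissions[1, AMINO_ACIDS.index("K")] == pytest.approx(expected_hit)
    off = model.match_emissions[0, AMINO_ACIDS.index("A")]
    assert off == pytest.approx(expected_miss)


def test_build_errors():
    with pytest.raises(ValueError, match="empty"):
        hmm.build_hmm([])
    with pytest.raises(ValueError, match="equal length"):
        hmm.build_hmm(["MADA", "MAD"])


# --- path-enumeration oracle ---------------------------------------------

def oracle_paths(model, seq):
    """All admissible path odds (log2) for the local-in-sequence topology:
    N-flank loops, entry B->M_k, match/insert/delete walk, exit M_k->E,
    C-flank loops.  Independent of the DP implementation."""
    x = [AMINO_ACIDS.index(c) for c in seq]
    L, M = len(x), model.n_states
    r = L / (L + 1.0)
    lo = np.log2(np.maximum(model.match_emissions, 1e-300)) - \
        np.log2(model.background)[None, :]
    li = np.log2(np.maximum(model.insert_emissions, 1e-300)) - \
        np.log2(model.background)[None, :]

    def log2p(p):
        return math.log2(p) if p > 0 else -math.inf

    results = []

    def walk(state, node, pos, acc):
        # state in {"M", "I", "D"}; `node` is 0-based; pos = residues used
        if state == "M":
            if pos >= L:
                return
            acc = acc + lo[node, x[pos]] - math.log2(r)
            pos += 1
            # exit here
            exit_odds = log2p(model.m_e[node])
            if exit_odds > -math.inf:
                results.append(acc + exit_odds)
            if node + 1 < M:
                if model.t_mm[node] > 0:
                    walk("M", node + 1, pos, acc + log2p(model.t_mm[node]))
                if model.t_md[node] > 0:
                    walk("D", node + 1, pos, acc + log2p(model.t_md[node]))
            if model.t_mi[node] > 0:
                walk("I", node, pos, acc + log2p(model.t_mi[node]))
        elif state == "I":
            if pos >= L:
                return
            acc = acc + li[node, x[pos]] - math.log2(r)
            pos += 1
            if model.t_im[node] > 0 and node + 1 < M:
                walk("M", node + 1, pos, acc + log2p(model.t_im[node]))
            if model.t_ii[node] > 0:
                walk("I", node, pos, acc + log2p(model.t_ii[node]))
        else:  # D
            if model.t_dm[node] > 0 and node + 1 < M:
                walk("M", node + 1, pos, acc + log2p(model.t_dm[node]))
            if model.t_dd[node] > 0 and node + 1 < M:
                walk("D", node + 1, pos, acc + log2p(model.t_dd[node]))

    entry_base = math.log2(1.0 - r)
    for start_pos in range(L):  # residues 0..start_pos-1 emitted by N flank
        for k in range(M):
            if model.b_m[k] > 0:
                walk("M", k, start_pos, entry_base + log2p(model.b_m[k]))
    # C flank consumes the remainder at odds 0, so any path that used
    # fewer than L residues is already accounted for.
    return results


@pytest.mark.parametrize("seq", ["MADA", "MAD", "WKADA", "MADAG"])
def test_forward_and_viterbi_match_path_enumeration(seq):
    """3-match-state toy model: forward equals log2 of the summed path
    odds; Viterbi equals the best path (<= 1e-9 in log space)."""
    model = hmm.build_hmm(["MAD", "MAD", "MCD"])
    paths = oracle_paths(model, seq)
    expected_forward = np.logaddexp2.reduce(paths)
    expected_viterbi = max(paths)
    vit = hmm.score_sequence(model, seq, "viterbi").score
    fwd = hmm.score_sequence(model, seq, "forward").score
    assert vit == pytest.approx(expected_viterbi, abs=1e-6)
    assert fwd == pytest.approx(expected_forward, abs=1e-6)


def test_generic_topology_with_inserts_and_deletes():
    """A hand-built model using insert and delete transitions still
    matches exhaustive path enumeration."""
    M = 3
    match = np.full((M, 20), 0.01)
    for i, aa in enumerate("MKL"):
        match[i, AMINO_ACIDS.index(aa)] = 1 - 0.01 * 19
    bg = np.full(20, 1.0 / 20)
    model = hmm.ProfileHMM(
        name="toy", match_emissions=match, insert_emissions=np.tile(bg, (M, 1)),
        background=bg,
        t_mm=np.array([0.7, 0.7, 0.0]), t_mi=np.array([0.1, 0.1, 0.0]),
        t_md=np.array([0.2, 0.1, 0.0]),
        t_im=np.array([0.6, 0.6, 0.6]), t_ii=np.array([0.4, 0.4, 0.4]),
        t_dm=np.array([1.0, 1.0, 1.0]), t_dd=np.array([0.0, 0.0, 0.0]),
        b_m=np.array([1.0, 0.0, 0.0]), m_e=np.array([0.0, 0.1, 1.0]),
    )
    for seq in ["MKL", "MKKL", "ML", "WMKLW"]:
        paths = oracle_paths(model, seq)
        fwd = hmm.score_sequence(model, seq, "forward").score
        vit = hmm.score_sequence(model, seq, "viterbi").score
        assert fwd == pytest.approx(np.logaddexp2.reduce(paths), abs=1e-6)
        assert vit == pytest.approx(max(paths), abs=1e-6)


def test_forward_at_least_viterbi():
    rng = np.random.default_rng(0)
    model = hmm.build_hmm(["MADAV", "MADAV", "MCDAV"])
    for _ in range(10):
        seq = random_protein(rng, int(rng.integers(5, 60)))
        vit = hmm.score_sequence(model, seq, "viterbi").score
        fwd = hmm.score_sequence(model, seq, "forward").score
        assert fwd >= vit - 1e-9


def test_hit_coordinates():
    model = hmm.build_hmm(["MADA"] * 5)
    hit = hmm.score_sequence(model, "GGGGMADAGGGG")
    assert (hit.start, hit.end) == (5, 8)
    assert hit.reported


def test_score_invariant_to_id_and_wrapping(tmp_path):
    from madascan.records import read_fasta, write_fasta

    model = hmm.build_hmm(["MADAV"] * 5)
    seq = "KKKMADAVKKK"
    rec1 = SequenceRecord(id="one", residues=seq)
    path = tmp_path / "wrap.fasta"
    path.write_text(">two\nKKK\nMADAVK\nKK\n")
    rec2 = read_fasta(path)[0]
    assert hmm.score_sequence(model, rec1).score == \
        hmm.score_sequence(model, rec2).score


def test_unknown_residue_scored_as_background():
    model = hmm.build_hmm(["MADA"] * 5)
    base = hmm.score_sequence(model, "GGGGMADAGGGG").score
    with pytest.warns(UserWarning, match="unknown residue"):
        odd = hmm.score_sequence(model, "GGGGMADAGGGG".replace("G", "B", 1))
    assert odd.score == pytest.approx(base, abs=0.1)


def test_x_is_score_neutral_inside_motif():
    model = hmm.build_hmm(["MADA"] * 5)
    full = hmm.score_sequence(model, "GGGGMADAGGGG").score
    masked = hmm.score_sequence(model, "GGGGMXDAGGGG").score
    assert masked < full  # lost one informative column, no penalty beyond


def test_synthetic_discrimination_zero_overlap():
    """An HMM from 20 planted sites (conservation 0.9) separates intact
    carriers from randomized N-termini with non-overlapping scores."""
    from madascan.simulate import SimConfig, generate_repertoire

    config = SimConfig(seed=21, n_families=1, seqs_per_family=20,
                       decoy_count=20, helper_motif_fraction=1.0,
                       motif_conservation=0.9, extension_jitter=0)
    records, truths = generate_repertoire(config)
    truth_of = {t.record_id: t for t in truths}
    sites = [r.residues[:21] for r in records if truth_of[r.id].role == "helper"]
    model = hmm.build_hmm(sites)
    helper_scores = [hmm.score_sequence(model, r).score for r in records
                     if truth_of[r.id].role == "helper"]
    decoy_scores = [hmm.score_sequence(model, r).score for r in records
                    if truth_of[r.id].role == "decoy"]
    assert min(helper_scores) > max(decoy_scores)


# --- classification -------------------------------------------------------

@pytest.mark.parametrize("score,expected", [
    (30.8, "MADA"),
    (10.0, "MADA"),   # boundary: >= rule
    (9.3, "MADAL"),
    (7.8, "MADAL"),
    (0.0, "none"),
    (-3.0, "none"),
])
def test_classify_rules(score, expected):
    hit = hmm.HmmHit(record_id="x", score=score, start=1, end=21,
                     reported=score > 0)
    assert hmm.classify(hit).label == expected
    assert hit.label == expected


def test_classify_respects_madal_floor():
    hit = hmm.HmmHit(record_id="x", score=3.0, start=1, end=21, reported=True)
    assert hmm.classify(hit, madal_floor=5.0).label == "none"


# --- calibration ----------------------------------------------------------

def test_gumbel_lambda_recovery_within_ten_percent():
    """Scores drawn from Gumbel(mu=0, lambda=0.7): the ML fit used by
    calibrate recovers lambda within 10% at n=5000."""
    from scipy import stats

    rng = np.random.default_rng(17)
    scores = stats.gumbel_r.rvs(loc=0.0, scale=1 / 0.7, size=5000,
                                random_state=rng)
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    assert abs(lam - 0.7) / 0.7 < 0.10
    assert abs(loc) < 0.2


def test_calibrate_deterministic_and_evalue_linear():
    model = hmm.build_hmm(["MADAVVSFKL"] * 8)
    c1 = hmm.calibrate(model, n_random=300, len_dist=120, seed=4)
    c2 = hmm.calibrate(model, n_random=300, len_dist=120, seed=4)
    assert (c1.evd_mu, c1.evd_lambda) == (c2.evd_mu, c2.evd_lambda)
    e1 = hmm.evalue(c1, 12.0, n_db=1000)
    e2 = hmm.evalue(c1, 12.0, n_db=2000)
    assert e2 == pytest.approx(2 * e1)


def test_calibrate_rejects_tiny_samples():
    model = hmm.build_hmm(["MADA"] * 5)
    with pytest.raises(ValueError, match="100"):
        hmm.calibrate(model, n_random=50)


def test_calibrated_null_matches_fit_distribution():
    """Fresh background scores exceed the fitted Gumbel's 95th percentile
    at roughly the nominal rate."""
    from scipy import stats

    rng = np.random.default_rng(14)
    sites = []
    word = "MADAVVSFKLWHEQNPRTGY"
    for _ in range(30):
        s = list(word)
        for i in range(len(s)):
            if rng.random() < 0.3:
                s[i] = AMINO_ACIDS[rng.integers(0, 20)]
        sites.append("".join(s))
    model = hmm.build_hmm(sites)
    cal = hmm.calibrate(model, n_random=2000, len_dist=200, seed=9)
    X = rng.choice(20, size=(1000, 200), p=model.background)
    scores = hmm._viterbi_scores_batch(model, X)
    fitted_q95 = stats.gumbel_r.ppf(0.95, loc=cal.evd_mu,
                                    scale=1 / cal.evd_lambda)
    exceed = float(np.mean(scores > fitted_q95))
    assert 0.01 < exceed < 0.15


# --- HMMER2 format --------------------------------------------------------

def test_hmmer2_roundtrip_identical_integers(tmp_path):
    model = hmm.build_hmm(["MADAVVSFKL"] * 7, name="round")
    model = hmm.calibrate(model, n_random=200, len_dist=80, seed=0)
    p1 = tmp_path / "a.hmm"
    p2 = tmp_path / "b.hmm"
    hmm.write_hmm(model, p1)
    back = hmm.read_hmm(p1)
    hmm.write_hmm(back, p2)
    assert p1.read_text() == p2.read_text()
    assert back.n_states == model.n_states
    assert back.evd_mu == pytest.approx(model.evd_mu, abs=1e-5)
    # decoded probabilities match to integer precision
    assert np.allclose(back.match_emissions, model.match_emissions, rtol=5e-4)


def test_hmmer2_missing_terminator(tmp_path):
    model = hmm.build_hmm(["MADA"] * 3)
    path = tmp_path / "trunc.hmm"
    hmm.write_hmm(model, path)
    text = path.read_text().rstrip().rsplit("//", 1)[0]
    path.write_text(text)
    with pytest.raises(hmm.Hmmer2ParseError, match="//"):
        hmm.read_hmm(path)


def test_hmmer2_not_a_save_file(tmp_path):
    path = tmp_path / "junk.hmm"
    path.write_text("HELLO\n")
    with pytest.raises(hmm.Hmmer2ParseError, match="HMMER2.0"):
        hmm.read_hmm(path)


def test_hmmer2_decode_formula_by_hand(tmp_path):
    """Hand-built two-state toy file: decoded probabilities equal the
    2^(score/1000) * null inversion."""
    nule = " ".join(["0"] * 20)  # null == uniform 1/20
    # node 1: p(M) = 0.05 * 2^2 = 0.2; the other 19 residues share 0.8,
    # i.e. score 1000*log2((0.8/19)/0.05) ~= -248
    match1 = ["-248"] * 20
    match1[AMINO_ACIDS.index("M")] = "2000"
    # node 2: p(K) = 1 -> score 1000*log2(20) ~= 4322; the rest are zero
    match2 = ["*"] * 20
    match2[AMINO_ACIDS.index("K")] = "4322"
    ins = ["0"] * 20
    lines = [
        "HMMER2.0  [test]",
        "NAME  toy", "LENG  2", "ALPH  Amino", "NSEQ  1",
        "NULE  " + nule,
        "HMM   ...", "      m->m ...",
        "     1 " + " ".join(match1),
        "     - " + " ".join(ins),
        "     - " + " ".join(["0", "*", "*", "*", "*", "*", "*", "0", "*"]),
        "     2 " + " ".join(match2),
        "     - " + " ".join(ins),
        "     - " + " ".join(["*", "*", "*", "*", "*", "*", "*", "*", "0"]),
        "//",
    ]
    path = tmp_path / "toy.hmm"
    path.write_text("\n".join(lines) + "\n")
    model = hmm.read_hmm(path)
    assert model.n_states == 2
    m_idx = AMINO_ACIDS.index("M")
    assert model.match_emissions[0, m_idx] == pytest.approx(
        (1 / 20) * 2 ** (2000 / 1000))
    a_idx = AMINO_ACIDS.index("A")
    assert model.match_emissions[0, a_idx] == pytest.approx(
        (1 / 20) * 2 ** (-248 / 1000))
    assert model.match_emissions[1, a_idx] == 0.0
    assert model.match_emissions[1, AMINO_ACIDS.index("K")] == pytest.approx(
        (1 / 20) * 2 ** (4322 / 1000))
    assert model.background[0] == pytest.approx(1 / 20)
    assert model.t_mm[0] == 1.0 and model.b_m[0] == 1.0 and model.m_e[1] == 1.0


def test_scan_agreement_with_pyhmmer_ranking():
    """Cross-validation against HMMER (pyhmmer): an independent HMM built
    from the same sites ranks intact carriers above background sequences
    exactly as this implementation does."""
    pyhmmer = pytest.importorskip("pyhmmer")
    rng = np.random.default_rng(33)
    word = "MADAEVSFAVGKLTKLLENEL"
    carriers = []
    for _ in range(10):
        s = list(word)
        for i in range(len(s)):
            if rng.random() < 0.1:
                s[i] = AMINO_ACIDS[rng.integers(0, 20)]
        carriers.append("".join(s) + random_protein(rng, 80))
    decoys = [random_protein(rng, 101) for _ in range(10)]
    sites = [c[:21] for c in carriers]
    mine = hmm.build_hmm(sites)
    my_scores = {f"s{i}": hmm.score_sequence(mine, s).score
                 for i, s in enumerate(carriers + decoys)}

    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = [pyhmmer.easel.TextSequence(name=f"site{i}".encode(), sequence=s)
            for i, s in enumerate(sites)]
    msa = pyhmmer.easel.TextMSA(name=b"sites", sequences=seqs).digitize(alphabet)
    builder = pyhmmer.plan7.Builder(alphabet)
    profile, _, _ = builder.build_msa(msa, pyhmmer.plan7.Background(alphabet))
    targets = pyhmmer.easel.DigitalSequenceBlock(
        alphabet,
        [pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=s).digitize(alphabet)
         for i, s in enumerate(carriers + decoys)])
    pipeline = pyhmmer.plan7.Pipeline(alphabet, bias_filter=False, F1=1.0,
                                      F2=1.0, F3=1.0)
    hits = pipeline.search_hmm(profile, targets)
    ref_scores = {(h.name.decode() if isinstance(h.name, bytes) else h.name):
                  h.score for h in hits}
    # every carrier outranks every decoy in both implementations
    my_carrier_min = min(my_scores[f"s{i}"] for i in range(10))
    my_decoy_max = max(my_scores[f"s{i}"] for i in range(10, 20))
    assert my_carrier_min > my_decoy_max
    ref_carriers = [ref_scores.get(f"s{i}", 0.0) for i in range(10)]
    ref_decoys = [ref_scores.get(f"s{i}", -10.0) for i in range(10, 20)]
    assert min(ref_carriers) > max(ref_decoys)


def test_profile_hmm_classifier_estimator():
    """The sklearn front end classifies carriers as MADA and noise as
    none, and clones cleanly."""
    from sklearn.base import clone

    rng = np.random.default_rng(12)
    sites = []
    word = "MADAEVSFAVGKLTKLLENEL"
    for _ in range(15):
        s = list(word)
        for i in range(len(s)):
            if rng.random() < 0.1:
                s[i] = AMINO_ACIDS[rng.integers(0, 20)]
        sites.append("".join(s))
    est = hmm.ProfileHmmClassifier(cutoff=10.0)
    est.fit(sites)
    carriers = [s + random_protein(rng, 50) for s in sites[:5]]
    noise = [random_protein(rng, 71) for _ in range(5)]
    labels = est.predict(carriers + noise)
    assert list(labels[:5]) == ["MADA"] * 5
    assert all(l in ("none", "MADAL") for l in labels[5:])
    scores = est.decision_function(carriers)
    assert (scores >= 10.0).all()
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
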