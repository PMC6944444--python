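"""ZOOPS expectation-maximization motif discovery.

The generative model per sequence: with probability ``gamma`` the
sequence contains exactly one motif occurrence at a uniformly chosen
start, emitted column-wise from a position weight matrix; all other
positions (and the whole sequence, with probability ``1 - gamma``) are
emitted from a 0-order background.  EM alternates posterior inference
over starts (plus the no-site class) with re-estimation of the PWM,
background and gamma; the data log-likelihood is non-decreasing.

Multiple motifs are reported MEME-style by masking: occurrences of each
reported motif are replaced by ``X`` and discovery repeats.  Masked
positions are unalignable — a candidate window overlapping a masked
region is excluded — so later motifs never overlap earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .records import AMINO_ACIDS

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MASK = "X"


@dataclass
class MotifModel:
    width: int
    pwm: np.ndarray  # (width, 20) probabilities
    background: np.ndarray  # (20,)
    zoops_gamma: float
    n_sites: int = 0
    log_likelihood: float = float("-inf")
    site_sequences: list[str] = field(default_factory=list)
    sub_threshold: bool = False

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.shape != (self.width, 20):
            raise ValueError("pwm must be (width, 20)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if not 0.0 < self.zoops_gamma <= 1.0:
            raise ValueError("zoops_gamma must lie in (0, 1]")

    def information_content(self) -> np.ndarray:
        """Per-column relative entropy (bits) of the PWM vs background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.pwm * (np.log2(self.pwm) - np.log2(self.background))
        return np.nan_to_num(terms, nan=0.0, posinf=0.0, neginf=0.0).sum(axis=1)


@dataclass
class MotifOccurrence:
    record_id: str
    start: int  # 1-based
    posterior: float
    matched: str


def _encode(seq: str) -> np.ndarray:
    """Residue codes; mask/unknown -> -1."""
    return np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def _composition(encoded: Sequence[np.ndarray], pseudo: float = 1.0) -> np.ndarray:
    counts = np.full(20, pseudo)
    for x in encoded:
        valid = x[x >= 0]
        counts += np.bincount(valid, minlength=20)
    return counts / counts.sum()


def _window_matrix(x: np.ndarray, width: int) -> np.ndarray:
    """(n_windows, width) of residue codes via a sliding view."""
    m = len(x) - width + 1
    if m <= 0:
        return np.empty((0, width), dtype=np.int64)
    return np.lib.stride_tricks.sliding_window_view(x, width)


def _e_step(log_pwm: np.ndarray, log_bg: np.ndarray, gamma: float,
            windows: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray, float]:
    """Posteriors over (no-site, starts) per sequence and total log-likelihood.

    Window log-scores are motif-vs-background log odds, so the shared
    background factor cancels; windows containing masked residues are
    excluded (log-odds -inf).
    """
    log_odds = log_pwm - log_bg[None, :]
    posteriors: list[np.ndarray] = []
    p_site = np.zeros(len(windows))
    total_ll = 0.0
    for idx, win in enumerate(windows):
        m = win.shape[0]
        if m == 0:
            posteriors.append(np.zeros(0))
            p_site[idx] = 0.0
            total_ll += np.log(1.0 - gamma) if gamma < 1.0 else -np.inf
            continue
        valid = np.all(win >= 0, axis=1)
        scores = np.full(m, -np.inf)
        if valid.any():
            w = win[valid]
            scores[valid] = log_odds[np.arange(log_pwm.shape[0])[None, :], w].sum(axis=1)
        log_terms = np.concatenate((
            [np.log(1.0 - gamma) if gamma < 1.0 else -np.inf],
            np.log(gamma / m) + scores,
        ))
        norm = logsumexp(log_terms)
        post = np.exp(log_terms - norm)
        posteriors.append(post[1:])
        p_site[idx] = post[1:].sum()
        total_ll += norm
    return posteriors, p_site, total_ll


def zoops_em_step(model: MotifModel, seqs: Sequence[str],
                  pseudocount: float = 0.01) -> tuple[MotifModel, float]:
    """One EM step.  Returns the updated model and the log-likelihood of
    the data under the *input* model (so repeated calls yield a monotone
    non-decreasing sequence)."""
    encoded = [_encode(s) for s in seqs]
    windows = [_window_matrix(x, model.width) for x in encoded]
    with np.errstate(divide="ignore"):
        log_pwm = np.log(model.pwm)
        log_bg = np.log(model.background)
    posteriors, p_site, ll = _e_step(log_pwm, log_bg, model.zoops_gamma, windows)

    w = model.width
    counts = np.full((w, 20), pseudocount)
    site_res_counts = np.zeros(20)
    col_idx = np.arange(w)
    for win, post in zip(windows, posteriors):
        if win.shape[0] == 0 or not np.any(post > 1e-12):
            continue
        keep = post > 1e-12
        sub, weights = win[keep], post[keep]
        ok = sub >= 0
        cols = np.broadcast_to(col_idx, sub.shape)[ok]
        res = sub[ok]
        wts = np.broadcast_to(weights[:, None], sub.shape)[ok]
        np.add.at(counts, (cols, res), wts)
        np.add.at(site_res_counts, res, wts)
    pwm = counts / counts.sum(axis=1, keepdims=True)

    total_res = np.full(20, 1.0)  # +1 smoothing
    for x in encoded:
        valid = x[x >= 0]
        total_res += np.bincount(valid, minlength=20)
    bg_counts = np.maximum(total_res - site_res_counts, pseudocount)
    background = bg_counts / bg_counts.sum()

    gamma = float(np.clip(np.mean(p_site), 1e-6, 1.0))
    updated = MotifModel(width=w, pwm=pwm, background=background,
                         zoops_gamma=gamma, n_sites=model.n_sites,
                         log_likelihood=ll)
    return updated, float(ll)


class ZoopsMotifEM(BaseEstimator):
    """ZOOPS EM motif finder (scikit-learn style).

    ``fit(X)`` takes a list of protein sequences; fitted attributes are
    ``pwm_``, ``background_``, ``gamma_``, ``log_likelihood_``,
    ``occurrences_`` (list of (sequence index, 0-based start, posterior))
    and ``model_``.  ``n_starts`` EM runs are launched from PWMs seeded
    on distinct input substrings chosen by the seeded RNG; the
    highest-likelihood run wins, so fits are deterministic for a fixed
    ``random_state``.
    """

    def __init__(self, width: int = 21, n_starts: int = 10, n_screen: int = 300,
                 max_iter: int = 100, tol: float = 1e-6, pseudocount: float = 0.01,
                 gamma_init: float = 0.5, random_state: int = 0):
        self.width = width
        self.n_starts = n_starts
        self.n_screen = n_screen
        self.max_iter = max_iter
        self.tol = tol
        self.pseudocount = pseudocount
        self.gamma_init = gamma_init
        self.random_state = random_state

    def _seed_pwm(self, window: np.ndarray) -> np.ndarray:
        pwm = np.full((self.width, 20), 0.4 / 19)
        for i, code in enumerate(window):
            if code >= 0:
                pwm[i] = 0.4 / 19
                pwm[i, code] = 0.6
            else:
                pwm[i] = 1.0 / 20
        return pwm / pwm.sum(axis=1, keepdims=True)

    def fit(self, X: Sequence[str], y=None):
        seqs = list(X)
        if any(len(s) < self.width for s in seqs):
            raise ValueError("every sequence must be at least `width` long")
        if self.width < 4:
            raise ValueError("width must be >= 4")
        encoded = [_encode(s) for s in seqs]
        windows = [_window_matrix(x, self.width) for x in encoded]
        background = _composition(encoded)
        rng = np.random.default_rng(self.random_state)

        # candidate seed substrings: mask-free windows across sequences
        candidates = []
        for si, win in enumerate(windows):
            for j in range(win.shape[0]):
                if np.all(win[j] >= 0):
                    candidates.append((si, j))
        if not candidates:
            raise ValueError("no mask-free windows available for seeding")

        # screening: one EM step from many substring seeds, then refine
        # only the most promising ones (MEME-style starting-point search)
        n_screen = min(self.n_screen, len(candidates))
        screened = rng.choice(len(candidates), size=n_screen, replace=False)
        scored_seeds = []
        for pick in screened:
            si, j = candidates[int(pick)]
            model = MotifModel(width=self.width, pwm=self._seed_pwm(windows[si][j]),
                               background=background, zoops_gamma=self.gamma_init)
            model, _ = zoops_em_step(model, seqs, self.pseudocount)
            _, _, ll = _e_step(np.log(np.maximum(model.pwm, 1e-300)),
                               np.log(np.maximum(model.background, 1e-300)),
                               model.zoops_gamma, windows)
            scored_seeds.append((ll, int(pick)))
        scored_seeds.sort(key=lambda t: (-t[0], t[1]))
        n_starts = min(self.n_starts, len(scored_seeds))
        picks = [pick for _, pick in scored_seeds[:n_starts]]

        best: Optional[MotifModel] = None
        best_ll = -np.inf
        for pick in picks:
            si, j = candidates[int(pick)]
            model = MotifModel(width=self.width, pwm=self._seed_pwm(windows[si][j]),
                               background=background, zoops_gamma=self.gamma_init)
            prev_ll = -np.inf
            for _ in range(self.max_iter):
                model, ll = zoops_em_step(model, seqs, self.pseudocount)
                if ll - prev_ll < self.tol and np.isfinite(prev_ll):
                    break
                prev_ll = ll
            _, _, final_ll = _e_step(np.log(np.maximum(model.pwm, 1e-300)),
                                     np.log(np.maximum(model.background, 1e-300)),
                                     model.zoops_gamma, windows)
            if final_ll > best_ll:
                best, best_ll = model, final_ll

        assert best is not None
        posteriors, _, _ = _e_step(np.log(np.maximum(best.pwm, 1e-300)),
                                   np.log(np.maximum(best.background, 1e-300)),
                                   best.zoops_gamma, windows)
        occurrences: list[tuple[int, int, float]] = []
        for si, post in enumerate(posteriors):
            if post.size == 0:
                continue
            j = int(np.argmax(post))
            if post[j] >= 0.5:
                occurrences.append((si, j, float(post[j])))
        self.model_ = best
        self.pwm_ = best.pwm
        self.background_ = best.background
        self.gamma_ = best.zoops_gamma
        self.log_likelihood_ = float(best_ll)
        self.occurrences_ = occurrences
        return self


def discover_motifs(seqs: dict[str, str] | Sequence[str], width: int,
                    n_motifs: int = 5, min_site_fraction: float = 0.7,
                    n_starts: int = 10, seed: int = 0,
                    max_iter: int = 100,
                    n_screen: int = 300) -> list[tuple[MotifModel, list[MotifOccurrence]]]:
    """MEME-style iterated discovery: fit a ZOOPS motif, report sites with
    posterior >= 0.5, mask them with ``X``, repeat ``n_motifs`` times.

    Motifs recovering fewer than ``min_site_fraction`` of the sequences
    are flagged ``sub_threshold`` but still reported.
    """
    if isinstance(seqs, dict):
        ids = list(seqs)
        working = [seqs[i] for i in ids]
    else:
        working = list(seqs)
        ids = [f"seq{i+1}" for i in range(len(working))]
    if width < 4:
        raise ValueError("width must be >= 4")
    if any(len(s) < width for s in working):
        raise ValueError("width exceeds the shortest sequence")

    results = []
    for round_idx in range(n_motifs):
        est = ZoopsMotifEM(width=width, n_starts=n_starts, n_screen=n_screen,
                           max_iter=max_iter, random_state=seed + round_idx)
        try:
            est.fit(working)
        except ValueError:
            break  # fully masked; nothing left to discover
        occurrences = []
        for si, j, post in est.occurrences_:
            occurrences.append(MotifOccurrence(
                record_id=ids[si], start=j + 1, posterior=post,
                matched=working[si][j : j + width]))
        model = est.model_
        model.n_sites = len(occurrences)
        model.site_sequences = [o.matched for o in occurrences]
        model.sub_threshold = len(occurrences) < min_site_fraction * len(working)
        results.append((model, occurrences))
        for si, j, _post in est.occurrences_:
            s = working[si]
            working[si] = s[:j] + MASK * width + s[j + width :]
    return results


def consensus_string(model: MotifModel, conserved_min: float = 0.45) -> str:
    """Per column: the most frequent residue if its frequency is at least
    ``conserved_min``, else ``x``.  Frequencies come from the reported
    site alignment when available, otherwise from the PWM."""
    if model.site_sequences:
        freqs = np.zeros((model.width, 20))
        for site in model.site_sequences:
            for i, c in enumerate(site):
                if c in _AA_INDEX:
                    freqs[i, _AA_INDEX[c]] += 1
        totals = np.maximum(freqs.sum(axis=1, keepdims=True), 1e-12)
        freqs = freqs / totals
    else:
        freqs = model.pwm
    out = []
    for col in freqs:
        j = int(np.argmax(col))
        out.append(AMINO_ACIDS[j] if col[j] >= conserved_min else "x")
    return "".join(out)


# --- I/O -----------------------------------------------------------------

def write_meme_minimal(models: Sequence[MotifModel], path: str | Path,
                       names: Optional[Sequence[str]] = None) -> None:
    """MEME minimal motif exchange format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AMINO_ACIDS + "\n\n")
        bg = models[0].background if models else np.full(20, 0.05)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{aa} {f:.6f}" for aa, f in zip(AMINO_ACIDS, bg)) + "\n\n")
        for k, model in enumerate(models):
            name = names[k] if names else f"MOTIF_{k+1}"
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 20 w= {model.width} "
                     f"nsites= {model.n_sites}\n")
            for row in model.pwm:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def occurrences_to_stockholm(occurrences: Sequence[MotifOccurrence],
                             path: str | Path) -> None:
    """Site alignment (ungapped, one row per occurrence) in Stockholm
    format — the input consumed by the profile-HMM builder."""
    if not occurrences:
        raise ValueError("no occurrences to write")
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max(len(o.record_id) for o in occurrences) + 12
        for o in occurrences:
            label = f"{o.record_id}/{o.start}-{o.start + len(o.matched) - 1}"
            fh.write(f"{label:<{width}}{o.matched}\n")
        fh.write("//\n")
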