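"""Promoter windows, ZOOPS motif discovery, PWM scanning, Alu enrichment.

Promoters are strand-specific windows from 2,000 bp upstream to 500 bp
downstream of a TFE peak (sequences in transcription orientation). Motif
discovery uses an EM fit of the ZOOPS model (each window carries zero or one
site at a uniform offset, against a 0-order background); scanning reports at
most one best site per window with an exact p-value from dynamic programming
over the discretized log-odds score distribution. Alu overlap enrichment is
tested by placing the same window set uniformly at random over the genome.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import GenomeModel, RepeatInterval, revcomp
from .tfe import TFE

ALPHABET = "ACGT"


def encode(seq: str) -> np.ndarray:
    out = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(ALPHABET):
        table[ord(b)] = i
    enc = table[out]
    if (enc < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return enc.astype(np.int64)


@dataclass
class PromoterWindow:
    tfe_id: str
    contig: str
    start: int
    end: int
    strand: str
    seq: str  # transcription orientation (reverse-complemented on '-')
    clipped: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PWM:
    """Position probability matrix with pseudocount bookkeeping."""

    probs: np.ndarray  # (W, 4), rows sum to 1
    site_count: int = 0
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be (W, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if (self.probs <= 0).any():
            raise ValueError("PWM entries must be positive (apply a pseudocount)")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_sites(cls, sites: Sequence[str], pseudocount: float = 0.01) -> "PWM":
        if not sites:
            raise ValueError("no sites")
        W = len(sites[0])
        counts = np.zeros((W, 4))
        for s in sites:
            counts[np.arange(W), encode(s)] += 1
        probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
        return cls(probs, site_count=len(sites), pseudocount=pseudocount)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        """Total information in bits relative to a uniform background."""
        return float((self.probs * np.log2(self.probs * 4.0)).sum())


@dataclass
class MotifHit:
    promoter_id: str
    offset: int
    score: float  # log2 odds vs background
    pvalue: float


@dataclass
class AluOverlap:
    promoter_id: str
    repeats: list[RepeatInterval] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.repeats)


def extract_promoter(
    tfe: TFE, genome: GenomeModel, up: int = 2000, down: int = 500
) -> PromoterWindow:
    """Strand-specific window [-up, +down) around the TFE peak.

    On '+' the genomic interval is [peak-up, peak+down); on '-' it is
    [peak-down+1, peak+up+1) and the sequence is reverse-complemented so the
    returned sequence always reads in transcription orientation. Windows are
    clipped at contig bounds (flag set).
    """
    if tfe.peak is None:
        raise ValueError(f"{tfe.id}: no peak assigned")
    contig_seq = genome.contig_seq(tfe.contig)
    if not 0 <= tfe.peak < len(contig_seq):
        raise ValueError(f"{tfe.id}: peak {tfe.peak} outside contig")
    if tfe.strand == "+":
        lo, hi = tfe.peak - up, tfe.peak + down
    else:
        lo, hi = tfe.peak - down + 1, tfe.peak + up + 1
    clipped = lo < 0 or hi > len(contig_seq)
    lo, hi = max(0, lo), min(len(contig_seq), hi)
    seq = contig_seq[lo:hi]
    if tfe.strand == "-":
        seq = revcomp(seq)
    return PromoterWindow(tfe.id, tfe.contig, lo, hi, tfe.strand, seq, clipped)


def _log_odds(pwm: PWM, background: np.ndarray) -> np.ndarray:
    return np.log2(pwm.probs / background[None, :])


def _discretize(log_odds: np.ndarray, grain: float) -> np.ndarray:
    return np.rint(log_odds / grain).astype(np.int64)


def score_distribution_pvalue(
    pwm: PWM, background: np.ndarray, observed_units: int, grain: float = 0.01
) -> float:
    """Exact tail probability of a per-position log-odds score.

    Scores are discretized to ``grain`` bits per column; the null score
    distribution is built by dynamic programming (column-wise convolution of
    the background-weighted discretized column scores), and the p-value is
    the total null mass at or above the observed discretized score.
    """
    units = _discretize(_log_odds(pwm, background), grain)
    offset = int(units.min(axis=1).sum())
    span = int((units.max(axis=1) - units.min(axis=1)).sum())
    dist = np.zeros(span + 1)
    dist[0] = 1.0
    lo = 0
    for w in range(pwm.width):
        col = units[w] - units[w].min()
        new = np.zeros_like(dist)
        for b in range(4):
            new[col[b] :] += background[b] * dist[: dist.size - col[b] if col[b] else dist.size]
        dist = new
        lo += int(units[w].min())
    # dist[k] = P(total units == offset + k)
    k0 = observed_units - offset
    if k0 <= 0:
        return 1.0
    if k0 > span:
        return 0.0
    return float(dist[k0:].sum())


def scan_pwm(
    window: PromoterWindow | str,
    pwm: PWM,
    background: Optional[np.ndarray] = None,
    p_threshold: float = 1e-10,
    grain: float = 0.01,
) -> Optional[MotifHit]:
    """Best single site of a PWM in a window (ZOOPS: at most one hit).

    The best-scoring offset is reported iff the exact per-position p-value
    of its score is below ``p_threshold``. Windows shorter than the motif
    yield no hit.
    """
    if isinstance(window, str):
        seq, pid = window, ""
    else:
        seq, pid = window.seq, window.tfe_id
    x = encode(seq)
    if x.size < pwm.width:
        return None
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    units = _discretize(_log_odds(pwm, bg), grain)
    win = np.lib.stride_tricks.sliding_window_view(x, pwm.width)
    scores_units = units[np.arange(pwm.width)[None, :], win].sum(axis=1)
    best = int(scores_units.argmax())
    pvalue = score_distribution_pvalue(pwm, bg, int(scores_units[best]), grain)
    if pvalue >= p_threshold:
        return None
    log_odds = _log_odds(pwm, bg)
    score = float(log_odds[np.arange(pwm.width), win[best]].sum())
    return MotifHit(pid, best, score, pvalue)


@dataclass
class ZoopsResult:
    pwm: PWM
    site_posteriors: np.ndarray  # per sequence: P(sequence carries a site)
    best_offsets: np.ndarray  # per sequence: argmax site offset
    gamma: float  # fitted fraction of sequences with a site
    log_likelihood: float
    llr_vs_background: float
    ll_trace: list[float]


def zoops_em_discover(
    windows: Sequence[PromoterWindow | str],
    width: int,
    n_seeds: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    pseudocount: float = 0.01,
    rng: Optional[np.random.Generator] = None,
) -> ZoopsResult:
    """EM fit of the ZOOPS motif model.

    Each sequence contains 0 or 1 site (prior gamma, offset uniform); the
    background is 0-order, estimated from the windows and held fixed. EM is
    restarted from the ``n_seeds`` most frequent W-mers and the best final
    likelihood wins. The log likelihood is non-decreasing across iterations.
    """
    if len(windows) == 0:
        raise ValueError("no windows")
    if width < 4:
        raise ValueError("motif width must be >= 4")
    seqs = [w if isinstance(w, str) else w.seq for w in windows]
    xs = [encode(s) for s in seqs]
    if any(x.size < width for x in xs):
        raise ValueError(f"all windows must be at least {width} bp")
    counts = np.bincount(np.concatenate(xs), minlength=4).astype(float)
    background = counts / counts.sum()

    ll_bg = float(sum(np.log(background[x]).sum() for x in xs))
    slid = [np.lib.stride_tricks.sliding_window_view(x, width) for x in xs]
    bg_site = [np.log(background[s]).sum(axis=1) for s in slid]

    best: Optional[ZoopsResult] = None
    for seed_kmer in _seed_kmers(xs, width, n_seeds):
        pwm_probs = np.full((width, 4), 0.1)
        pwm_probs[np.arange(width), seed_kmer] = 0.7
        gamma = 0.5
        trace: list[float] = []
        for _ in range(max_iter):
            log_pwm = np.log(pwm_probs)
            # E-step
            post_site = np.zeros(len(xs))  # P(seq has a site)
            z_list = []
            ll = 0.0
            for i, s in enumerate(slid):
                m = s.shape[0]
                site_ll = log_pwm[np.arange(width)[None, :], s].sum(axis=1)
                # per-offset joint: gamma/m * P(seq | site at j); no-site: (1-gamma)
                log_terms = np.concatenate(
                    [[np.log1p(-gamma) if gamma < 1 else -np.inf],
                     np.log(gamma / m) + site_ll - bg_site[i]]
                )
                mx = log_terms.max()
                probs = np.exp(log_terms - mx)
                tot = probs.sum()
                ll += mx + np.log(tot) + float(np.log(background[xs[i]]).sum())
                z = probs[1:] / tot
                post_site[i] = z.sum()
                z_list.append(z)
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
                break
            # M-step
            weighted = np.zeros((width, 4))
            for i, s in enumerate(slid):
                z = z_list[i]
                for b in range(4):
                    weighted[:, b] += (z[:, None] * (s == b)).sum(axis=0)
            denom = post_site.sum() + 4 * pseudocount
            pwm_probs = (weighted + pseudocount) / denom
            pwm_probs /= pwm_probs.sum(axis=1, keepdims=True)
            gamma = float(np.clip(post_site.mean(), 1e-6, 1 - 1e-6))
        offsets = np.array([int(z.argmax()) for z in z_list])
        result = ZoopsResult(
            PWM(pwm_probs, site_count=int(round(post_site.sum())), pseudocount=pseudocount),
            post_site,
            offsets,
            gamma,
            trace[-1],
            trace[-1] - ll_bg,
            trace,
        )
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    assert best is not None
    return best


def _seed_kmers(xs: Sequence[np.ndarray], width: int, n_seeds: int) -> list[np.ndarray]:
    """Most frequent distinct W-mers across the windows (EM start points)."""
    from collections import Counter

    counter: Counter = Counter()
    for x in xs:
        s = np.lib.stride_tricks.sliding_window_view(x, width)
        for row in s[:: max(1, s.shape[0] // 500)]:  # subsample long windows
            counter[tuple(row)] += 1
    top = [np.array(k) for k, _ in counter.most_common(n_seeds)]
    return top if top else [np.zeros(width, dtype=int)]


def _overlap_counts(
    starts: np.ndarray, ends: np.ndarray, win_start: np.ndarray, win_end: np.ndarray
) -> np.ndarray:
    """Number of intervals overlapping each window by >= 1 bp.

    With starts/ends sorted independently: overlaps = #{start < window end}
    - #{end <= window start}, exact for any interval set.
    """
    return np.searchsorted(starts, win_end, side="left") - np.searchsorted(
        ends, win_start, side="right"
    )


def alu_overlap(
    windows: Sequence[PromoterWindow], repeats: Sequence[RepeatInterval]
) -> list[AluOverlap]:
    """Per-window list of repeat intervals with >= 1 bp genomic overlap."""
    by_contig: dict[str, list[RepeatInterval]] = {}
    for r in repeats:
        by_contig.setdefault(r.contig, []).append(r)
    out = []
    for w in windows:
        hits = [
            r
            for r in by_contig.get(w.contig, [])
            if r.start < w.end and r.end > w.start
        ]
        out.append(AluOverlap(w.tfe_id, hits))
    return out


def alu_enrichment_test(
    windows: Sequence[PromoterWindow],
    repeats: Sequence[RepeatInterval],
    genome: GenomeModel,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    exclude_contig_prefix: str = "SPIKE",
) -> tuple[float, float, float]:
    """Window-permutation test of repeat overlap enrichment.

    Observed = mean repeat count over the real windows. The null places the
    same-size window set uniformly at random over the genome (windows fit
    fully inside a contig), ``n_perm`` times;
    p = (1 + #{null mean >= observed}) / (n_perm + 1).
    """
    if not windows:
        raise ValueError("no promoter windows")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng or np.random.default_rng()
    observed = float(np.mean([o.count for o in alu_overlap(windows, repeats)]))

    contigs = [
        (name, len(seq))
        for name, seq in genome.contigs
        if not name.startswith(exclude_contig_prefix)
    ]
    lengths = np.array([w.length for w in windows])
    sorted_by_contig = {}
    for name, _ in contigs:
        rs = sorted(r.start for r in repeats if r.contig == name)
        re_ = sorted(r.end for r in repeats if r.contig == name)
        sorted_by_contig[name] = (np.array(rs), np.array(re_))

    total = sum(max(0, clen - int(lengths.max())) for _, clen in contigs)
    if total <= 0:
        raise ValueError("genome too small to place random windows")
    names = [n for n, _ in contigs]
    weights = np.array([max(0, clen - int(lengths.max())) for _, clen in contigs], dtype=float)
    weights /= weights.sum()

    null_means = np.empty(n_perm)
    for p in range(n_perm):
        ci = rng.choice(len(names), size=len(windows), p=weights)
        counts = np.empty(len(windows))
        for k in range(len(names)):
            mask = ci == k
            if not mask.any():
                continue
            clen = contigs[k][1]
            ws = rng.integers(0, clen - lengths[mask] + 1)
            starts, ends = sorted_by_contig[names[k]]
            counts[mask] = _overlap_counts(starts, ends, ws, ws + lengths[mask])
        null_means[p] = counts.mean()
    pvalue = (1.0 + float((null_means >= observed).sum())) / (n_perm + 1.0)
    return observed, float(null_means.mean()), pvalue
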