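"""Maximum-likelihood estimation of the ctDNA fraction and the MRD score.

Model
-----
Plasma cell-free DNA is treated as a two-component mixture: a fraction
``alpha`` derives from tumor, the rest from normal background.  At a selected
methylation block *j* with tumor methylation rate ``p_T_j`` and background
rate ``p_N_j``, a plasma read is methylated with probability

    theta_j(alpha) = alpha * p_T_j + (1 - alpha) * p_N_j,

and the methylated read count is k_j ~ Binomial(n_j, theta_j(alpha)).
``alpha`` — the MD ratio — is estimated by maximizing the binomial
log-likelihood over [0, 1].  Because theta_j is linear in alpha and the
binomial log-likelihood is concave in theta, the problem is concave and the
maximizer unique up to flat stretches; flat ties resolve to the smallest
alpha (conservative toward the null).

Inference
---------
The Fisher information of alpha is

    I(alpha) = sum_j n_j * (p_T_j - p_N_j)^2 / (theta_j * (1 - theta_j)),

the plug-in variance of the estimate is 1 / I(alpha_hat), and the MRD score
is the Wald statistic alpha_hat * sqrt(I(alpha_hat)) for the null
alpha = 0.  A sample is MRD-positive when the score strictly exceeds 1.96
(the standard-normal upper 2.5% point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .cohort_io import BlockCounts, ValidationError
from .mb_selection import MBSet, RATE_EPS, clamp_rate

MRD_WALD_THRESHOLD = 1.96

# alpha differences below this are treated as a flat-likelihood tie
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class MixtureBlock:
    """One block's plasma counts plus the rates that anchor the mixture."""

    block_id: str
    k: int
    n: int
    p_tumor: float
    p_normal: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValidationError(f"block {self.block_id}: need 0 <= k <= n, got k={self.k}, n={self.n}")
        object.__setattr__(self, "p_tumor", clamp_rate(self.p_tumor))
        object.__setattr__(self, "p_normal", clamp_rate(self.p_normal))


@dataclass(frozen=True)
class MDEstimate:
    """Fitted MD ratio with its Wald machinery and fit bookkeeping."""

    alpha_hat: float
    variance: float
    wald: float
    loglik_at_max: float
    n_blocks_used: int
    n_reads_used: int


@dataclass(frozen=True)
class MRDCall:
    sample_id: str
    estimate: MDEstimate
    positive: bool
    threshold: float = MRD_WALD_THRESHOLD


def mixture_rate(alpha: float, p_tumor: float, p_normal: float) -> float:
    """Methylated-read probability of the two-component mixture, clamped."""
    return clamp_rate(alpha * p_tumor + (1.0 - alpha) * p_normal)


def _as_arrays(blocks: Sequence[MixtureBlock]):
    k = np.array([b.k for b in blocks], dtype=float)
    n = np.array([b.n for b in blocks], dtype=float)
    pt = np.array([b.p_tumor for b in blocks], dtype=float)
    pn = np.array([b.p_normal for b in blocks], dtype=float)
    return k, n, pt, pn


def _loglik(alpha: float, k: np.ndarray, n: np.ndarray, pt: np.ndarray, pn: np.ndarray) -> float:
    theta = np.clip(alpha * pt + (1.0 - alpha) * pn, RATE_EPS, 1.0 - RATE_EPS)
    return float(np.sum(k * np.log(theta) + (n - k) * np.log1p(-theta)))


def log_likelihood(alpha: float, blocks: Sequence[MixtureBlock]) -> float:
    """Binomial mixture log-likelihood at ``alpha`` (coefficients dropped)."""
    if not blocks:
        raise ValidationError("log_likelihood needs at least one block")
    return _loglik(alpha, *_as_arrays(blocks))


def fisher_information(alpha: float, blocks: Sequence[MixtureBlock]) -> float:
    """Expected information about alpha carried by the blocks' read counts."""
    if not blocks:
        return 0.0
    _, n, pt, pn = _as_arrays(blocks)
    theta = np.clip(alpha * pt + (1.0 - alpha) * pn, RATE_EPS, 1.0 - RATE_EPS)
    return float(np.sum(n * (pt - pn) ** 2 / (theta * (1.0 - theta))))


def mrd_score(alpha_hat: float, information: float) -> float:
    """Wald statistic for H0: alpha = 0; zero on the boundary or without information."""
    if alpha_hat <= 0.0 or information <= 0.0:
        return 0.0
    return alpha_hat * math.sqrt(information)


def fit_md_ratio(blocks: Sequence[MixtureBlock]) -> MDEstimate:
    """Maximum-likelihood fit of the MD ratio over alpha in [0, 1].

    Blocks with no reads are dropped (they contribute nothing to the
    likelihood); a likelihood that is flat in alpha (all p_T ~= p_N) returns
    the null point alpha=0 with infinite variance and score 0.
    """
    usable = [b for b in blocks if b.n > 0]
    if not blocks or sum(b.n for b in blocks) == 0:
        raise ValidationError("no informative reads: every block has n = 0")
    k, n, pt, pn = _as_arrays(usable)
    n_reads = int(n.sum())

    informative = np.abs(pt - pn) > 10 * RATE_EPS
    if not informative.any():
        return MDEstimate(
            alpha_hat=0.0,
            variance=math.inf,
            wald=0.0,
            loglik_at_max=_loglik(0.0, k, n, pt, pn),
            n_blocks_used=len(usable),
            n_reads_used=n_reads,
        )

    opt = minimize_scalar(
        lambda a: -_loglik(a, k, n, pt, pn),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    # evaluate boundary candidates; prefer the smallest alpha on ties
    alpha_hat, best_ll = 0.0, _loglik(0.0, k, n, pt, pn)
    for cand in (float(opt.x), 1.0):
        ll = _loglik(cand, k, n, pt, pn)
        if ll > best_ll + _TIE_TOL:
            alpha_hat, best_ll = cand, ll

    info = fisher_information(alpha_hat, usable)
    variance = 1.0 / info if info > 0 else math.inf
    return MDEstimate(
        alpha_hat=alpha_hat,
        variance=variance,
        wald=mrd_score(alpha_hat, info),
        loglik_at_max=best_ll,
        n_blocks_used=len(usable),
        n_reads_used=n_reads,
    )


def grid_search_md_ratio(blocks: Sequence[MixtureBlock], step: float = 1e-4) -> float:
    """Brute-force grid maximizer of the log-likelihood (reference oracle).

    Evaluates alpha on {0, step, 2*step, ..., 1} and returns the smallest
    argmax.  Slow but independent of the scalar optimizer; used to validate
    ``fit_md_ratio``.
    """
    usable = [b for b in blocks if b.n > 0]
    if not usable:
        raise ValidationError("no informative reads: every block has n = 0")
    k, n, pt, pn = _as_arrays(usable)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    theta = np.clip(grid[:, None] * pt + (1.0 - grid[:, None]) * pn, RATE_EPS, 1.0 - RATE_EPS)
    ll = (k * np.log(theta) + (n - k) * np.log1p(-theta)).sum(axis=1)
    return float(grid[int(np.argmax(ll))])


def call_mrd(sample_id: str, estimate: MDEstimate, threshold: float = MRD_WALD_THRESHOLD) -> MRDCall:
    """MRD positivity: score strictly greater than the threshold."""
    return MRDCall(
        sample_id=sample_id,
        estimate=estimate,
        positive=estimate.wald > threshold,
        threshold=threshold,
    )


def mixture_blocks(mbset: MBSet, plasma_blocks: Iterable[BlockCounts]) -> list[MixtureBlock]:
    """Join a patient's selected blocks with one plasma sample's counts.

    Blocks in the MBSet absent from the plasma table are skipped (panel
    dropouts); plasma blocks outside the MBSet are ignored.
    """
    counts = {b.block_id: b for b in plasma_blocks}
    joined: list[MixtureBlock] = []
    for sel in mbset.blocks:
        bc = counts.get(sel.block_id)
        if bc is None:
            continue
        joined.append(
            MixtureBlock(
                block_id=sel.block_id,
                k=bc.methylated_reads,
                n=bc.total_reads,
                p_tumor=sel.p_tumor,
                p_normal=sel.p_normal,
            )
        )
    return joined
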