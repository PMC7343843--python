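"""Autosome/X assignment of contigs from female:male coverage ratios.

In an XY system a female carries two X copies and a male one, so the
female-to-male relative median depth ratio ρ of a contig is expected near 1
for autosomes and near 2 for X-linked sequence.  The ρ distribution over
contigs is modeled as a two-component equal-variance Gaussian mixture fit
by EM, and each contig is called autosomal or X-linked only when the
alternative component can be rejected (its two-sided tail probability at ρ
falls below ``alpha_level``); contigs implausible under both components
stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthetic import DepthTrack

__all__ = [
    "ContigCoverageProfile",
    "GmmFit",
    "ContigAssignment",
    "subsample_depth",
    "contig_rho",
    "filter_contigs",
    "em_gmm_2class",
    "classify",
    "assign_contigs",
]


@dataclass
class ContigCoverageProfile:
    """Subsampled, outlier-trimmed depths for one contig in one individual."""

    contig: str
    positions: np.ndarray
    depths: np.ndarray
    median_depth: float
    n_positions: int


@dataclass
class GmmFit:
    """Two-component, equal-variance 1-D Gaussian mixture fit (mu1 < mu2)."""

    mu1: float
    mu2: float
    sigma: float
    weights: tuple[float, float]
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


@dataclass
class ContigAssignment:
    contig: str
    rho: float
    cls: str  # autosome | X | unassigned | filtered
    p_other: float
    filter_reason: str = ""


def subsample_depth(
    tracks: Iterable[DepthTrack],
    step: int = 100,
    percentile_cut: float = 0.999,
) -> tuple[dict[str, ContigCoverageProfile], float]:
    """Thin depth tracks and trim extreme positions for one individual.

    Every ``step``-th position of each contig is retained; retained
    positions whose depth strictly exceeds the individual's genome-wide
    ``percentile_cut`` quantile (computed over retained positions of all
    contigs) are then discarded.  Returns the per-contig profiles and the
    individual's genome-wide median depth (over retained, trimmed
    positions).
    """
    kept: list[tuple[str, np.ndarray, np.ndarray]] = []
    for track in tracks:
        pos = track.get_positions()
        dep = np.asarray(track.depths)
        kept.append((track.contig, pos[::step].copy(), dep[::step].astype(np.float64)))
    if not kept:
        return {}, float("nan")
    all_depths = np.concatenate([d for _, _, d in kept])
    cutoff = np.quantile(all_depths, percentile_cut) if len(all_depths) else np.inf
    profiles: dict[str, ContigCoverageProfile] = {}
    trimmed: list[np.ndarray] = []
    for contig, pos, dep in kept:
        keep = dep <= cutoff
        pos, dep = pos[keep], dep[keep]
        trimmed.append(dep)
        profiles[contig] = ContigCoverageProfile(
            contig=contig,
            positions=pos,
            depths=dep,
            median_depth=float(np.median(dep)) if len(dep) else float("nan"),
            n_positions=int(len(dep)),
        )
    genome_median = float(np.median(np.concatenate(trimmed)))
    return profiles, genome_median


def contig_rho(
    profile_f: ContigCoverageProfile,
    profile_m: ContigCoverageProfile,
    genome_median_f: float,
    genome_median_m: float,
) -> float:
    """Female:male relative median coverage ratio of one contig.

    ρ = (median_f / genome_median_f) / (median_m / genome_median_m);
    invariant under global rescaling of either individual's depths.
    """
    if genome_median_f <= 0 or genome_median_m <= 0:
        raise ValueError("genome-wide median depths must be positive")
    if profile_m.median_depth <= 0:
        raise ValueError(
            f"{profile_m.contig}: zero male median coverage (should have been filtered)"
        )
    rel_f = profile_f.median_depth / genome_median_f
    rel_m = profile_m.median_depth / genome_median_m
    return rel_f / rel_m


def filter_contigs(
    profiles_f: Mapping[str, ContigCoverageProfile],
    profiles_m: Mapping[str, ContigCoverageProfile],
    min_m: float = 5.0,
    min_f: float = 2.0,
    min_positions: int = 100,
) -> dict[str, str]:
    """Identify contigs to exclude before the mixture fit.

    A contig is filtered when (a) its male median depth is below ``min_m``
    or female median below ``min_f``; (b) fewer than ``min_positions``
    retained positions in either individual; or (c) its median depth is an
    outlier above Q3 + 1.5·IQR of the contig-median distribution in either
    individual.  Returns contig -> reason for the filtered ones.
    """
    reasons: dict[str, str] = {}
    contigs = [c for c in profiles_f if c in profiles_m]
    med_f = np.array([profiles_f[c].median_depth for c in contigs])
    med_m = np.array([profiles_m[c].median_depth for c in contigs])

    def _upper_fence(x: np.ndarray) -> float:
        q1, q3 = np.percentile(x[~np.isnan(x)], [25, 75])
        return q3 + 1.5 * (q3 - q1)

    fence_f = _upper_fence(med_f)
    fence_m = _upper_fence(med_m)
    for c, mf, mm in zip(contigs, med_f, med_m):
        if np.isnan(mm) or mm < min_m:
            reasons[c] = "low male coverage"
        elif np.isnan(mf) or mf < min_f:
            reasons[c] = "low female coverage"
        elif (
            profiles_f[c].n_positions < min_positions
            or profiles_m[c].n_positions < min_positions
        ):
            reasons[c] = "too few analyzed positions"
        elif mf > fence_f or mm > fence_m:
            reasons[c] = "outlying coverage"
    return reasons


def em_gmm_2class(
    rhos: Sequence[float],
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int | None = None,
) -> GmmFit:
    """Fit a two-component equal-variance Gaussian mixture to ρ values by EM.

    Initialization is deterministic at means (1.0, 2.0) — the biological
    expectations for autosomes and the X — with equal weights and the
    sample standard deviation; ``seed`` is accepted for interface
    stability but unused by this deterministic scheme.  Convergence:
    log-likelihood gain below ``tol``.  The log-likelihood trace is
    non-decreasing (an EM guarantee, asserted in tests).
    """
    x = np.asarray(rhos, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all observations identical")
    mu = np.array([1.0, 2.0])
    sigma = max(float(np.std(x)), 1e-3)
    w = np.array([0.5, 0.5])
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (log-space for stability)
        logpdf = norm.logpdf(x[:, None], loc=mu[None, :], scale=sigma) + np.log(w)[None, :]
        m = logpdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logpdf - m).sum(axis=1))
        loglik = float(lse.sum())
        resp = np.exp(logpdf - lse[:, None])
        trace.append(loglik)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        # M-step (shared variance)
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-12):
            raise ValueError("degenerate fit: a component lost all responsibility")
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = float((resp * (x[:, None] - mu[None, :]) ** 2).sum() / len(x))
        sigma = max(np.sqrt(var), 1e-8)
        w = nk / len(x)
    if mu[0] > mu[1]:
        mu = mu[::-1]
        w = w[::-1]
    return GmmFit(
        mu1=float(mu[0]),
        mu2=float(mu[1]),
        sigma=float(sigma),
        weights=(float(w[0]), float(w[1])),
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
    )


def classify(
    contig: str, rho: float, fit: GmmFit, alpha_level: float = 0.01
) -> ContigAssignment:
    """Call one contig autosome/X/unassigned from its ρ and the mixture fit.

    The candidate class is the component with the larger posterior
    responsibility at ρ.  The call is confirmed only when the OTHER
    component's two-sided Gaussian tail probability at ρ is below
    ``alpha_level`` (the alternative is rejected); if ρ is also implausible
    under the candidate component — both tails below ``alpha_level`` — the
    contig stays unassigned rather than being force-called.
    """
    mus = np.array([fit.mu1, fit.mu2])
    ws = np.array(fit.weights)
    logp = norm.logpdf(rho, loc=mus, scale=fit.sigma) + np.log(ws)
    cand = int(np.argmax(logp))
    other = 1 - cand
    tail = lambda mu: 2.0 * norm.sf(abs(rho - mu) / fit.sigma)
    p_other = float(tail(mus[other]))
    p_cand = float(tail(mus[cand]))
    labels = ("autosome", "X")
    if p_other < alpha_level and p_cand >= alpha_level:
        cls = labels[cand]
    else:
        cls = "unassigned"
    return ContigAssignment(contig=contig, rho=rho, cls=cls, p_other=p_other)


def assign_contigs(
    tracks_f: Iterable[DepthTrack],
    tracks_m: Iterable[DepthTrack],
    step: int = 100,
    percentile_cut: float = 0.999,
    min_m: float = 5.0,
    min_f: float = 2.0,
    min_positions: int = 100,
    alpha_level: float = 0.01,
) -> tuple[pd.DataFrame, GmmFit]:
    """End-to-end sex-linkage assignment from raw per-position depth tracks.

    Subsamples and trims both individuals' tracks, filters unreliable
    contigs, computes ρ per remaining contig, fits the mixture and
    classifies.  Returns a per-contig table (contig, n_positions, median_f,
    median_m, rho, class, p_other, filter_reason) and the mixture fit.
    """
    profiles_f, genome_f = subsample_depth(tracks_f, step=step, percentile_cut=percentile_cut)
    profiles_m, genome_m = subsample_depth(tracks_m, step=step, percentile_cut=percentile_cut)
    reasons = filter_contigs(
        profiles_f, profiles_m, min_m=min_m, min_f=min_f, min_positions=min_positions
    )
    rows = []
    rhos: dict[str, float] = {}
    for contig in profiles_f:
        if contig not in profiles_m:
            continue
        pf, pm = profiles_f[contig], profiles_m[contig]
        if contig in reasons:
            rows.append((contig, pf.n_positions, pf.median_depth, pm.median_depth,
                         np.nan, "filtered", np.nan, reasons[contig]))
            continue
        rho = contig_rho(pf, pm, genome_f, genome_m)
        rhos[contig] = rho
    fit = em_gmm_2class(list(rhos.values()))
    for contig, rho in rhos.items():
        pf, pm = profiles_f[contig], profiles_m[contig]
        call = classify(contig, rho, fit, alpha_level=alpha_level)
        rows.append((contig, pf.n_positions, pf.median_depth, pm.median_depth,
                     rho, call.cls, call.p_other, ""))
    table = pd.DataFrame(
        rows,
        columns=["contig", "n_positions", "median_f", "median_m",
                 "rho", "class", "p_other", "filter_reason"],
    )
    return table.sort_values("contig", kind="stable").reset_index(drop=True), fit
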