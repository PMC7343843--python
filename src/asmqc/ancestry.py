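"""Local-ancestry painting of a haploid assembly with a two-state HMM.

An assembly derived from an admixed population is a mosaic of chromosomal
segments inherited from its two source populations (here labelled C and H,
for the Chinese and Hawaiian sources of the modeled system).  At each
ancestry-informative SNP (AIM) the emission probability of the observed
assembly allele under state C (resp. H) is its Laplace-smoothed frequency
in the C (resp. H) source pool; hidden ancestry follows a stationary
first-order chain with a constant per-adjacent-AIM switch probability tau.
Forward-backward posteriors give the admixture fraction alpha (mean
posterior P(C)); the Viterbi path gives the segment mosaic; tau and the
initial-state probability are fitted by Baum-Welch EM with emissions held
fixed (they are data-determined frequencies, not free parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HmmParams",
    "AncestryResult",
    "biallelic_filter",
    "laplace_freq",
    "aim_select",
    "forward_backward",
    "viterbi",
    "baum_welch",
    "paint_and_summarize",
]


@dataclass
class HmmParams:
    """Two-state ancestry chain parameters: stay 1-tau, switch tau."""

    pi_C: float = 0.5
    tau: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 0.5:
            raise ValueError("tau must lie in (0, 0.5)")
        if not 0.0 <= self.pi_C <= 1.0:
            raise ValueError("pi_C must lie in [0, 1]")


@dataclass
class AncestryResult:
    """Posterior painting, Viterbi segments and admixture summaries."""

    posteriors: dict[str, np.ndarray]          # contig -> P(C) per AIM
    viterbi_paths: dict[str, np.ndarray]       # contig -> 1 (C) / 0 (H)
    segments: pd.DataFrame                     # contig, start, end, state, mean_posterior
    alpha_per_contig: dict[str, float]
    alpha_per_class: dict[str, float]
    alpha_sd_per_class: dict[str, float]
    skipped_contigs: list[str] = field(default_factory=list)


def biallelic_filter(
    aims: pd.DataFrame, min_depth: int = 20, max_depth: int = 250
) -> np.ndarray:
    """Keep mask for bi-allelic SNPs at acceptable depth in both pools.

    Expects columns ref_count_C, depth_C, ref_count_H, depth_H (counts of
    the assembly/reference allele and total depths) and, optionally,
    other_count — reads supporting any third allele across pools, which
    disqualify a site.  A site is kept iff exactly two alleles are observed
    across the pools (both the reference and the alternate seen at least
    once, no third allele) and each pool's depth d satisfies
    min_depth < d < max_depth (both strict).
    """
    dC = aims["depth_C"].to_numpy()
    dH = aims["depth_H"].to_numpy()
    refC = aims["ref_count_C"].to_numpy()
    refH = aims["ref_count_H"].to_numpy()
    ref_seen = (refC + refH) > 0
    alt_seen = ((dC - refC) + (dH - refH)) > 0
    keep = ref_seen & alt_seen
    if "other_count" in aims.columns:
        keep &= aims["other_count"].to_numpy() == 0
    keep &= (dC > min_depth) & (dC < max_depth)
    keep &= (dH > min_depth) & (dH < max_depth)
    return keep


def laplace_freq(ref_count, depth):
    """Add-one (Laplace) frequency estimate (x+1)/(n+2), strictly in (0,1)."""
    ref_count = np.asarray(ref_count, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0) or np.any(ref_count < 0) or np.any(ref_count > depth):
        raise ValueError("require 0 <= ref_count <= depth and depth > 0")
    out = (ref_count + 1.0) / (depth + 2.0)
    return float(out) if out.ndim == 0 else out


def aim_select(aims: pd.DataFrame, min_diff: float = 0.2) -> pd.DataFrame:
    """Retain the most ancestry-informative SNPs.

    Adds Laplace-smoothed reference-allele frequencies ``p_C`` and ``p_H``
    and keeps sites with |p_C - p_H| strictly above ``min_diff``, ordered
    by contig and position.
    """
    out = aims.copy()
    out["p_C"] = laplace_freq(out["ref_count_C"], out["depth_C"])
    out["p_H"] = laplace_freq(out["ref_count_H"], out["depth_H"])
    keep = np.abs(out["p_C"] - out["p_H"]) > min_diff
    return out.loc[keep].sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)


def _emissions(aims: pd.DataFrame) -> np.ndarray:
    """Per-AIM emission probabilities of the observed assembly allele,
    shape (L, 2) with column 0 = state C, column 1 = state H."""
    return np.column_stack([aims["p_C"].to_numpy(), aims["p_H"].to_numpy()])


def forward_backward(
    aims: pd.DataFrame, params: HmmParams
) -> tuple[np.ndarray, float, np.ndarray]:
    """Scaled forward-backward over one contig's AIMs.

    Returns (posterior P(C) per AIM, total data log-likelihood, xi_sum)
    where xi_sum is the 2x2 matrix of expected transition counts (used by
    Baum-Welch).  Stable for millions of AIMs via per-step scaling.
    """
    if len(aims) == 0:
        raise ValueError("empty AIM list")
    e = _emissions(aims)  # (L, 2)
    L = len(e)
    eC = e[:, 0].tolist()
    eH = e[:, 1].tolist()
    tau = params.tau
    stay = 1.0 - tau

    # scaled forward pass (scalar arithmetic: the 2-state recursion is
    # sequential, so per-step numpy overhead would dominate)
    aC_arr = np.empty(L)
    aH_arr = np.empty(L)
    scale = np.empty(L)
    aC = params.pi_C * eC[0]
    aH = (1.0 - params.pi_C) * eH[0]
    s = aC + aH
    aC_arr[0], aH_arr[0], scale[0] = aC / s, aH / s, s
    aC, aH = aC / s, aH / s
    for t in range(1, L):
        pC = aC * stay + aH * tau
        pH = aC * tau + aH * stay
        aC = pC * eC[t]
        aH = pH * eH[t]
        s = aC + aH
        aC, aH = aC / s, aH / s
        aC_arr[t], aH_arr[t], scale[t] = aC, aH, s
    loglik = float(np.sum(np.log(scale)))

    # scaled backward pass with transition-count accumulation
    bC_arr = np.empty(L)
    bH_arr = np.empty(L)
    bC = bH = 1.0
    bC_arr[-1] = bH_arr[-1] = 1.0
    x00 = x01 = x10 = x11 = 0.0
    scale_l = scale.tolist()
    aC_l = aC_arr.tolist()
    aH_l = aH_arr.tolist()
    for t in range(L - 2, -1, -1):
        wC = eC[t + 1] * bC  # e*beta at t+1
        wH = eH[t + 1] * bH
        inv = 1.0 / scale_l[t + 1]
        x00 += aC_l[t] * stay * wC * inv
        x01 += aC_l[t] * tau * wH * inv
        x10 += aH_l[t] * tau * wC * inv
        x11 += aH_l[t] * stay * wH * inv
        bC = (stay * wC + tau * wH) * inv
        bH = (tau * wC + stay * wH) * inv
        bC_arr[t], bH_arr[t] = bC, bH
    gC = aC_arr * bC_arr
    gH = aH_arr * bH_arr
    posterior_C = gC / (gC + gH)
    xi_sum = np.array([[x00, x01], [x10, x11]])
    return posterior_C, loglik, xi_sum


def viterbi(aims: pd.DataFrame, params: HmmParams) -> np.ndarray:
    """Most probable state path over one contig's AIMs (1 = C, 0 = H)."""
    if len(aims) == 0:
        raise ValueError("empty AIM list")
    loge = np.log(_emissions(aims))
    L = len(loge)
    leC = loge[:, 0].tolist()
    leH = loge[:, 1].tolist()
    lstay = float(np.log1p(-params.tau))
    lswitch = float(np.log(params.tau))
    lpi = np.log(np.clip([params.pi_C, 1 - params.pi_C], 1e-300, None))
    dC = float(lpi[0]) + leC[0]
    dH = float(lpi[1]) + leH[0]
    back = np.empty((L, 2), dtype=np.int8)
    for t in range(1, L):
        fromC_C, fromH_C = dC + lstay, dH + lswitch
        fromC_H, fromH_H = dC + lswitch, dH + lstay
        if fromC_C >= fromH_C:
            back[t, 0], dC_new = 0, fromC_C
        else:
            back[t, 0], dC_new = 1, fromH_C
        if fromC_H >= fromH_H:
            back[t, 1], dH_new = 0, fromC_H
        else:
            back[t, 1], dH_new = 1, fromH_H
        dC = dC_new + leC[t]
        dH = dH_new + leH[t]
    states = np.empty(L, dtype=np.int8)
    states[-1] = 0 if dC >= dH else 1
    for t in range(L - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    # internal state index 0 = C; flip to 1 = C / 0 = H for the caller
    return (states == 0).astype(np.int8)


def baum_welch(
    aims: pd.DataFrame,
    init: HmmParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[HmmParams, list[float]]:
    """Fit tau and pi_C by EM with emissions held fixed.

    ``aims`` may span several contigs (column ``contig``); each contig is
    an independent chain sharing the parameters.  tau is clamped to
    [1e-8, 0.5 - 1e-8] if the update collapses to a boundary.  Returns the
    fitted parameters and the (non-decreasing) log-likelihood trace.
    """
    params = init or HmmParams()
    groups = [grp for _, grp in aims.groupby("contig", sort=True)]
    trace: list[float] = []
    lo, hi = 1e-8, 0.5 - 1e-8
    for _ in range(max_iter):
        total_ll = 0.0
        xi_tot = np.zeros((2, 2))
        gamma0 = []
        n_trans = 0
        for grp in groups:
            gC, ll, xi = forward_backward(grp, params)
            total_ll += ll
            xi_tot += xi
            gamma0.append(gC[0])
            n_trans += len(grp) - 1
        trace.append(total_ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        tau_new = (xi_tot[0, 1] + xi_tot[1, 0]) / max(n_trans, 1)
        if not lo <= tau_new <= hi:
            import warnings

            warnings.warn("tau update hit a boundary; clamped", RuntimeWarning)
        params = HmmParams(
            pi_C=float(np.clip(np.mean(gamma0), 0.0, 1.0)),
            tau=float(np.clip(tau_new, lo, hi)),
        )
    return params, trace


def paint_and_summarize(
    aims: pd.DataFrame,
    params: HmmParams,
    contig_classes: Mapping[str, str] | None = None,
) -> AncestryResult:
    """Posterior-paint every contig and summarize admixture fractions.

    alpha per contig is the mean posterior P(C) over its AIMs; per-class
    alpha is the AIM-count-weighted mean of per-contig alphas and alpha_sd
    the (unweighted) standard deviation of per-contig alphas within the
    class.  Viterbi paths are converted to bp segments with boundaries at
    midpoints between adjacent AIMs of different states.
    """
    contig_classes = contig_classes or {}
    posteriors: dict[str, np.ndarray] = {}
    paths: dict[str, np.ndarray] = {}
    alpha_c: dict[str, float] = {}
    n_aims: dict[str, int] = {}
    seg_rows = []
    skipped: list[str] = []
    for contig, grp in aims.groupby("contig", sort=True):
        if len(grp) == 0:
            skipped.append(contig)
            continue
        gC, _, _ = forward_backward(grp, params)
        path = viterbi(grp, params)
        posteriors[contig] = gC
        paths[contig] = path
        alpha_c[contig] = float(np.mean(gC))
        n_aims[contig] = len(grp)
        pos = grp["pos"].to_numpy()
        change = np.nonzero(np.diff(path))[0]
        boundaries = ((pos[change] + pos[change + 1]) // 2 + 1).tolist()
        starts = [int(pos[0])] + boundaries
        ends = boundaries + [int(pos[-1]) + 1]
        idx_start = [0] + (change + 1).tolist()
        idx_end = (change + 1).tolist() + [len(path)]
        for s, t, i0, i1 in zip(starts, ends, idx_start, idx_end):
            state = "C" if path[i0] == 1 else "H"
            seg_rows.append((contig, s, t, state, float(np.mean(gC[i0:i1]))))
    segments = pd.DataFrame(
        seg_rows, columns=["contig", "start", "end", "state", "mean_posterior"]
    )

    by_class: dict[str, list[str]] = {}
    for contig in alpha_c:
        by_class.setdefault(contig_classes.get(contig, "Unknown"), []).append(contig)
    alpha_class: dict[str, float] = {}
    alpha_sd: dict[str, float] = {}
    for cls, contigs in by_class.items():
        a = np.array([alpha_c[c] for c in contigs])
        w = np.array([n_aims[c] for c in contigs], dtype=float)
        alpha_class[cls] = float(np.average(a, weights=w))
        alpha_sd[cls] = float(np.std(a, ddof=1)) if len(a) > 1 else float("nan")
    return AncestryResult(
        posteriors=posteriors,
        viterbi_paths=paths,
        segments=segments,
        alpha_per_contig=alpha_c,
        alpha_per_class=alpha_class,
        alpha_sd_per_class=alpha_sd,
        skipped_contigs=skipped,
    )
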