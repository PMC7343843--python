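"""Synthetic data generators for every pipeline input.

Each generator emulates the statistical structure one analysis stage
assumes, and returns a :class:`SyntheticTruth` record so recovery can be
tested against known ground truth:

* :func:`gen_genome_with_duplications` — random contigs with annotated
  exons, some of which have a near-identical copy planted in tandem a short
  distance downstream (the collapsed-duplication assembly-error signature).
* :func:`gen_sex_coverage` — negative-binomial per-position read depth for
  one female and one male, with X-linked contigs at half relative depth in
  the male (XY dosage).
* :func:`gen_pool_counts` — neutral infinite-sites pooled allele counts:
  segregating-site count Poisson with mean theta * L * a(n), pool allele
  counts from the 1/i neutral frequency spectrum, read counts binomial.
* :func:`gen_ancestry_mosaic` — a two-state Markov ancestry path over
  ancestry-informative SNPs with divergent source-pool frequencies, plus
  pooled read counts for both source populations.

All generators are deterministic given their seed (numpy Generator,
PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping

import json
import numpy as np
import pandas as pd

from .dupexon import ExonRecord

__all__ = [
    "SyntheticTruth",
    "DepthTrack",
    "harmonic_number",
    "gen_genome_with_duplications",
    "gen_sex_coverage",
    "iter_sex_coverage",
    "gen_pool_counts",
    "gen_ancestry_mosaic",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticTruth:
    """Ground-truth record emitted by every generator."""

    scenario_id: str
    seed: int
    planted_duplications: list = field(default_factory=list)
    contig_classes: dict = field(default_factory=dict)
    theta_true: float | None = None
    ancestry_path: list = field(default_factory=list)
    alpha_true: float | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class DepthTrack:
    """Per-position read depth along one contig.

    Positions are 0-based; when ``positions`` is None they are implicit:
    ``start + step * arange(len(depths))``.
    """

    contig: str
    depths: np.ndarray
    step: int = 1
    start: int = 0
    positions: np.ndarray | None = None

    def get_positions(self) -> np.ndarray:
        if self.positions is not None:
            return self.positions
        return self.start + self.step * np.arange(len(self.depths), dtype=np.int64)


def harmonic_number(n: int) -> float:
    """a(n) = sum_{k=1}^{n-1} 1/k, the Watterson harmonic factor."""
    if n < 2:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, n)))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply ``n_subs`` random substitutions (each to a different base)."""
    if n_subs == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def gen_genome_with_duplications(
    n_contigs: int = 2,
    contig_length: int = 100_000,
    n_exons: int = 20,
    n_planted: int = 3,
    dup_length: int = 1000,
    exon_length: int = 200,
    max_substitutions: int = 2,
    max_insert_gap: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, str], list[ExonRecord], SyntheticTruth]:
    """Random contigs with exon annotations and planted tandem duplications.

    ``n_planted`` of the ``n_exons`` exons (each of length ``dup_length``;
    the rest are ``exon_length`` bp) receive a near-identical copy — 0 to
    ``max_substitutions`` random substitutions — spliced into the contig at
    most ``max_insert_gap`` bp (< 5 kb) downstream and annotated as a
    distinct exon of its own gene.  Exons never overlap.  Raises if the
    contigs are too crowded to place everything.
    """
    if dup_length >= contig_length:
        raise ValueError("dup_length must be smaller than contig_length")
    if n_planted > n_exons:
        raise ValueError("cannot plant more duplications than exons")
    if not 0 < max_insert_gap <= 5000 - 1:
        raise ValueError("max_insert_gap must lie in (0, 5000)")
    rng = np.random.default_rng(seed)

    # spread exons over contigs round-robin
    exon_contig = [i % n_contigs for i in range(n_exons)]
    planted_idx = set(rng.choice(n_exons, size=n_planted, replace=False).tolist())
    lengths = [dup_length if i in planted_idx else exon_length for i in range(n_exons)]

    contigs: dict[str, str] = {}
    exons: list[ExonRecord] = []
    truth = SyntheticTruth(scenario_id="genome_with_duplications", seed=seed)
    exon_no = 0
    for c in range(n_contigs):
        name = f"contig_{c+1}"
        seq = _random_seq(rng, contig_length)
        idxs = [i for i in range(n_exons) if exon_contig[i] == c]
        # budget per exon: its length + room for a duplicate copy + spacing
        need = sum(
            lengths[i] + (dup_length + max_insert_gap if i in planted_idx else 0) + 6000
            for i in idxs
        )
        if need > contig_length:
            raise ValueError(
                f"{name}: cannot place {len(idxs)} exons with duplications in "
                f"{contig_length} bp (needs ~{need})"
            )
        cursor = 0
        free_per_exon = (contig_length - need) // max(len(idxs), 1)
        out_pos = 0  # position in output (post-insertion) sequence
        new_seq_parts: list[str] = []
        prev = 0
        for i in idxs:
            gap_before = int(rng.integers(500, max(501, free_per_exon + 500)))
            start = cursor + gap_before
            end = start + lengths[i]
            if end > contig_length:
                raise ValueError(f"{name}: exon placement overflow")
            exon_seq = seq[start:end]
            new_seq_parts.append(seq[prev:end])
            out_start = out_pos + (start - prev)
            out_end = out_start + lengths[i]
            out_pos += end - prev
            prev = end
            exon_no += 1
            eid = f"exon_{exon_no}"
            gid = f"gene_{exon_no}"
            exons.append(
                ExonRecord(eid, name, out_start, out_end, "+", f"tr_{exon_no}", gid, exon_seq)
            )
            cursor = end
            if i in planted_idx:
                n_subs = int(rng.integers(0, max_substitutions + 1))
                copy_seq = _mutate(exon_seq, n_subs, rng)
                insert_gap = int(rng.integers(50, max_insert_gap + 1))
                filler = seq[end : end + insert_gap]
                new_seq_parts.append(filler)
                new_seq_parts.append(copy_seq)
                out_pos += insert_gap
                copy_start = out_pos
                copy_end = copy_start + len(copy_seq)
                out_pos += len(copy_seq)
                prev = end + insert_gap
                cursor = end + insert_gap
                exon_no += 1
                cid = f"exon_{exon_no}"
                exons.append(
                    ExonRecord(
                        cid, name, copy_start, copy_end, "+",
                        f"tr_{exon_no}", f"gene_{exon_no}", copy_seq,
                    )
                )
                truth.planted_duplications.append(
                    {
                        "contig": name,
                        "source_exon": eid,
                        "copy_exon": cid,
                        "source_interval": [out_start, out_end],
                        "insertion_point": copy_start,
                        "n_substitutions": n_subs,
                    }
                )
        new_seq_parts.append(seq[prev:contig_length])
        contigs[name] = "".join(new_seq_parts)
    return contigs, exons, truth


def _nb_draws(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with given mean and dispersion k (var = m + m^2/k)."""
    if not np.isfinite(dispersion):
        return rng.poisson(mean, size=size).astype(np.uint16)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.uint16)


def iter_sex_coverage(
    contig_classes: Mapping[str, str],
    contig_lengths: Mapping[str, int] | int,
    mean_depth_f: float = 18.0,
    mean_depth_m: float = 21.0,
    dispersion: float = 5.0,
    step: int = 1,
    seed: int = 0,
) -> Iterator[tuple[DepthTrack, DepthTrack]]:
    """Stream per-contig (female, male) depth tracks without holding the
    whole genome in memory.  See :func:`gen_sex_coverage`."""
    if mean_depth_f <= 0 or mean_depth_m <= 0:
        raise ValueError("mean depths must be positive")
    rng = np.random.default_rng(seed)
    for contig in contig_classes:
        cls = contig_classes[contig]
        if cls not in ("autosome", "X"):
            raise ValueError(f"unknown contig class {cls!r} for {contig}")
        length = contig_lengths if isinstance(contig_lengths, int) else contig_lengths[contig]
        n = length // step
        mean_m = mean_depth_m / 2.0 if cls == "X" else mean_depth_m
        depths_f = _nb_draws(rng, mean_depth_f, dispersion, n)
        depths_m = _nb_draws(rng, mean_m, dispersion, n)
        yield (
            DepthTrack(contig, depths_f, step=step),
            DepthTrack(contig, depths_m, step=step),
        )


def gen_sex_coverage(
    contig_classes: Mapping[str, str],
    contig_lengths: Mapping[str, int] | int,
    mean_depth_f: float = 18.0,
    mean_depth_m: float = 21.0,
    dispersion: float = 5.0,
    step: int = 1,
    seed: int = 0,
) -> tuple[dict[str, DepthTrack], dict[str, DepthTrack], SyntheticTruth]:
    """Sex-dosage coverage tracks for one female and one male.

    Depths are negative-binomial (mean/dispersion parameterization;
    ``dispersion=inf`` gives the Poisson limit).  X-class contigs use half
    the male mean (one X copy in the male) and the full female mean;
    autosomes use the full means in both.  Emitting one value every
    ``step`` bp at ``step>1`` thins the track at generation time.
    """
    tracks_f: dict[str, DepthTrack] = {}
    tracks_m: dict[str, DepthTrack] = {}
    for tf, tm in iter_sex_coverage(
        contig_classes, contig_lengths, mean_depth_f, mean_depth_m, dispersion, step, seed
    ):
        tracks_f[tf.contig] = tf
        tracks_m[tm.contig] = tm
    truth = SyntheticTruth(
        scenario_id="sex_coverage", seed=seed, contig_classes=dict(contig_classes)
    )
    return tracks_f, tracks_m, truth


def gen_pool_counts(
    theta_true: float,
    n_pool: int = 50,
    mean_depth: float = 50.0,
    n_sites: int = 100_000,
    contig: str = "contig_1",
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Neutral infinite-sites pooled allele counts over ``n_sites`` positions.

    The number of segregating sites is Poisson with mean
    ``theta_true * n_sites * a(n_pool)``; each segregating site's pool
    allele count i is drawn from the neutral spectrum P(i) ∝ 1/i,
    i = 1..n_pool-1; per-site depth is Poisson(``mean_depth``) and alt read
    counts are binomial(depth, i/n_pool).  Non-segregating sites are
    emitted as monomorphic.  Columns: contig, pos, ref, alt, ref_count,
    alt_count (pos 0-based).
    """
    if n_pool < 2:
        raise ValueError("n_pool must be >= 2")
    if theta_true < 0 or theta_true > 0.05:
        raise ValueError("theta_true must lie in [0, 0.05] (infinite-sites regime)")
    rng = np.random.default_rng(seed)
    a_n = harmonic_number(n_pool)
    n_seg = rng.poisson(theta_true * n_sites * a_n)
    n_seg = min(n_seg, n_sites)
    seg_pos = np.sort(rng.choice(n_sites, size=n_seg, replace=False))
    # neutral SFS P(i) ∝ 1/i over 1..n_pool-1
    i_vals = np.arange(1, n_pool)
    sfs = (1.0 / i_vals) / a_n
    counts = rng.choice(i_vals, size=n_seg, p=sfs)

    depth = rng.poisson(mean_depth, size=n_sites)
    alt = np.zeros(n_sites, dtype=np.int64)
    alt[seg_pos] = rng.binomial(depth[seg_pos], counts / n_pool)
    base_u1 = _BASES.astype("U1")
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_base = np.full(n_sites, ".", dtype="U1")
    if n_seg:
        alt_idx = (ref_idx[seg_pos] + rng.integers(1, 4, size=n_seg)) % 4
        alt_base[seg_pos] = base_u1[alt_idx]
    df = pd.DataFrame(
        {
            "contig": contig,
            "pos": np.arange(n_sites, dtype=np.int64),
            "ref": base_u1[ref_idx],
            "alt": alt_base,
            "ref_count": depth - alt,
            "alt_count": alt,
        }
    )
    truth = SyntheticTruth(
        scenario_id="pool_counts",
        seed=seed,
        theta_true=float(theta_true),
        extra={
            "n_segregating": int(n_seg),
            "pool_allele_counts": counts.tolist(),
            "seg_positions": seg_pos.tolist(),
        },
    )
    return df, truth


def gen_ancestry_mosaic(
    n_aims: int = 20_000,
    switch_prob: float = 1e-3,
    alpha_target: float = 0.78,
    freq_divergence: float = 0.5,
    depth: float = 50.0,
    aim_spacing: int = 500,
    contig: str = "contig_1",
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """An ancestry mosaic over ancestry-informative SNPs (AIMs).

    The hidden path is a stationary two-state Markov chain over states
    C and H with stationary P(C) = ``alpha_target`` and unconditional
    per-step switch probability ``switch_prob`` (transition rates
    s/(2·alpha) out of C and s/(2·(1−alpha)) out of H).  Per AIM, true
    source frequencies of an arbitrary allele are drawn with
    |p_C − p_H| ≥ ``freq_divergence``; the observed assembly allele is
    drawn from the frequency of the AIM's true state, and pooled read
    counts for both sources are binomial at ``depth`` (Poisson per site).

    Returned frame columns (one row per AIM, positions ``aim_spacing`` bp
    apart): contig, pos, ref, alt, ref_count_C, depth_C, ref_count_H,
    depth_H, where "ref" is the assembly (observed) allele and counts are
    of that allele.
    """
    if not 0 <= switch_prob < 0.5:
        raise ValueError("switch_prob must lie in [0, 0.5)")
    if not 0 < alpha_target < 1:
        raise ValueError("alpha_target must lie in (0, 1)")
    if freq_divergence <= 0.2:
        raise ValueError("freq_divergence must exceed 0.2 (the AIM retention filter)")
    t_ch = switch_prob / (2.0 * alpha_target)          # P(C -> H)
    t_hc = switch_prob / (2.0 * (1.0 - alpha_target))  # P(H -> C)
    if max(t_ch, t_hc) >= 1.0:
        raise ValueError("switch_prob too large for the requested alpha_target")
    rng = np.random.default_rng(seed)
    # hidden path: 1 = C, 0 = H
    u = rng.random(n_aims)
    path = np.empty(n_aims, dtype=np.int8)
    path[0] = 1 if u[0] < alpha_target else 0
    for i in range(1, n_aims):
        if path[i - 1] == 1:
            path[i] = 0 if u[i] < t_ch else 1
        else:
            path[i] = 1 if u[i] < t_hc else 0

    # true source frequencies of allele A1 with |p_C - p_H| >= divergence
    margin = 1.0 - freq_divergence
    lo = rng.random(n_aims) * margin
    hi = lo + freq_divergence + rng.random(n_aims) * (1.0 - freq_divergence - lo)
    c_high = rng.random(n_aims) < 0.5
    pC = np.where(c_high, hi, lo)
    pH = np.where(c_high, lo, hi)

    # observed assembly allele drawn from the true state's frequency
    p_state = np.where(path == 1, pC, pH)
    obs_is_a1 = rng.random(n_aims) < p_state
    # re-express frequencies as frequencies of the observed (assembly) allele
    pC_obs = np.where(obs_is_a1, pC, 1.0 - pC)
    pH_obs = np.where(obs_is_a1, pH, 1.0 - pH)

    depth_C = rng.poisson(depth, size=n_aims)
    depth_H = rng.poisson(depth, size=n_aims)
    ref_C = rng.binomial(depth_C, pC_obs)
    ref_H = rng.binomial(depth_H, pH_obs)

    base_u1 = _BASES.astype("U1")
    ref_idx = rng.integers(0, 4, size=n_aims)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_aims)) % 4
    ref_base = base_u1[ref_idx]
    alt_base = base_u1[alt_idx]

    df = pd.DataFrame(
        {
            "contig": contig,
            "pos": np.arange(n_aims, dtype=np.int64) * aim_spacing,
            "ref": ref_base,
            "alt": alt_base,
            "ref_count_C": ref_C,
            "depth_C": depth_C,
            "ref_count_H": ref_H,
            "depth_H": depth_H,
        }
    )
    truth = SyntheticTruth(
        scenario_id="ancestry_mosaic",
        seed=seed,
        ancestry_path=["C" if s == 1 else "H" for s in path],
        alpha_true=float(np.mean(path)),
    )
    return df, truth
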