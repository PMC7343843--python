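"""Segment a per-window rate track into high-rate regions by hysteresis.

A region opens on >=5 consecutive 10-kb windows above 0.005 and closes on
>=5 consecutive windows below 0.001; intermediate rates neither open nor
close, so regions are robust to local dips.
"""

from asmqc import hysteresis_segment

# a track with one clean region, an intermediate shoulder, and noise
rates = (
    [0.0002] * 10
    + [0.007] * 6          # opening run
    + [0.003] * 8          # intermediate: stays open
    + [0.0004] * 6         # closing run
    + [0.006] * 3          # too short to re-open
    + [0.0] * 7
)
regions = hysteresis_segment(rates, contig="ctg_1")

for r in regions:
    print(f"{r.contig}: {r.start:,}-{r.end:,} bp "
          f"({r.n_windows} windows, mean rate {r.mean_rate:.4f})")
# Expected: a single region spanning the opening run plus the intermediate
# shoulder (windows 10-23, i.e. 100,000-240,000 bp); the 3-window burst
# near the end never opens a region.
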