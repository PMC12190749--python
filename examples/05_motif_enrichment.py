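"""Footprint-restricted motif enrichment against matched controls.

Foreground and control footprint sequences share the same GC
composition (both are promoter footprints); a GC-box motif is planted at
40% of foreground and 5% of control footprints.  Each PWM is scanned on
both strands at an exact per-position p-value threshold of 1e-4 and
region hits are compared with a one-sided Fisher exact test.
"""

from markdyn.motifs import enrich_motifs, gc_content
from markdyn.simulate import simulate_motif_sequences, toy_pwms

fg, bg, fg_planted, bg_planted = simulate_motif_sequences(
    n_fg=300, n_bg=300, plant_rate_fg=0.4, plant_rate_bg=0.05, rng=5
)
fg_gc, _ = gc_content(fg)
bg_gc, _ = gc_content(bg)
print(f"foreground GC {fg_gc:.3f} vs control GC {bg_gc:.3f} (class-matched)")
print(f"planted instances: {fg_planted.sum()} foreground, {bg_planted.sum()} control")

result = enrich_motifs(fg, bg, toy_pwms(), scan_p=1e-4)
print(f"\n{'motif':<12}{'fg hits':>8}{'bg hits':>8}{'odds':>8}{'p':>12}{'q':>12}")
for row in result.itertuples():
    print(f"{row.motif_id:<12}{row.fg_hit_regions:>8}{row.bg_hit_regions:>8}"
          f"{row.odds_ratio:>8.2f}{row.fisher_p:>12.2e}{row.bh_q:>12.2e}")
# The planted GC-box should top the table by orders of magnitude while the
# unplanted decoys stay non-significant: the control-matched background
# absorbs the shared GC composition, so composition alone cannot score.
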