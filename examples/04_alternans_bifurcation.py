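"""Pacing a CRU-lattice myocyte: Ca2+ alternans from slowed troponin unbinding.

Paces the control (troponin k_off = 0.5 ms^-1) and slowed-unbinding
(k_off = 0.1 ms^-1) variants of the stochastic Ca2+-release-unit lattice
at a 400-ms cycle length and compares the last recorded beat peaks, then
runs a small bifurcation scan. Slowing Ca2+ unbinding from troponin keeps
Ca2+ on the myofilaments into diastole, delays SR refilling and pushes
short cycle lengths into period-2 (alternans) dynamics.

The full 300-700 ms scan with 5-seed majority voting is what
scripts/acceptance.py runs; this example keeps one seed and a coarse grid
so it finishes in a few minutes.
"""

import numpy as np

from alternans import crusim

protocol = crusim.PacingProtocol(pcl=400.0, n_beats=26, n_discard=20)
for variant in ("control", "reduced_koff"):
    params = crusim.make_default_params(variant, scale="test")
    trace = crusim.run_paced(params, protocol, seed=1)
    ratio, flag = crusim.detect_alternans(trace.beat_peaks)
    peaks = ", ".join(f"{p:.3f}" for p in trace.beat_peaks)
    print(f"{variant:13s} PCL=400 ms  peaks [uM] = {peaks}")
    print(f"{'':13s} alternans ratio = {ratio:.3f}  flag = {flag}")

grid = [350.0, 650.0]
for variant in ("control", "reduced_koff"):
    params = crusim.make_default_params(variant, scale="test")
    scan = crusim.scan_pcl(params, grid, seeds=[1])
    flags = {int(p): bool(f) for p, f in zip(scan.pcl_values, scan.alternans_flags)}
    print(f"{variant:13s} alternans by PCL: {flags}")
print()
print(
    "Equal last-two peaks mean a period-1 rhythm; a >5% split is flagged as"
    " alternans. The reduced-k_off variant alternates at short cycle"
    " lengths while the control stays period-1 across the grid."
)
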