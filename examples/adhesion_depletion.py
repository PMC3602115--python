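"""Pair stability when the adhesion scale is depleted over the run.

The adhesion energy scale decays as sigma(t) = sigma0 * (1 - (t/T)^p):
small exponents p deplete adhesion quickly, large p keep it near sigma0
until late in the run; every law reaches zero at t = T.  Cases I and II
are compared at a traction strength inside the transition window.

What to look for: faster depletion (smaller p) lowers the companion time,
and the effect is stronger for persistent sites (case I) than for dynamic
traction sites (case II), which keep rejoining while some adhesion
remains.  At zero traction pairs never break regardless of p: with no
propulsion the cells cannot move apart even as adhesion vanishes.
"""

from adhesim import ExperimentSpec, ModelParams, run_depletion_sweep

base = ModelParams()
f_lr = 5e-4  # inside the break-up transition at reference parameters
exponents = [0.5, 1.0, 2.0, 4.0]

for case in ("I", "II"):
    spec = ExperimentSpec(
        base=base,
        points=tuple(
            {"f_lr": f_lr, "decay_exponent": p} for p in exponents
        ) + ({"f_lr": f_lr, "decay_exponent": None},),
        runs_per_point=8,
        case=case,
        base_seed=300,
    )
    res = run_depletion_sweep(spec)
    print(f"\ncase {case} at f_lr={f_lr:g}:")
    print(f"{'p':>8} {'frac_broke':>10} {'mean_ct':>9} {'2*sem_ct':>9}")
    for point, s in zip(res.points, res.summaries):
        p = point["decay_exponent"]
        label = "const" if p is None else f"{p:g}"
        print(f"{label:>8} {s.frac_broke:>10.2f} {s.mean_ct:>9.2f} "
              f"{s.sem2_ct:>9.2f}")
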