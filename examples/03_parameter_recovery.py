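"""Parameter recovery: how well does the G study estimate known components?

Simulates many replications from the LAST/MH behavioural preset at two
design sizes and reports bias and RMSE of the raw component estimates.
"""

from gcross import SimulationSpec, recovery_experiment

for n_p, n_t, n_r, reps in [(10, 2, 2, 400), (200, 20, 10, 60)]:
    spec = SimulationSpec.from_preset(
        "last_mh_behavioural", n_p=n_p, n_t=n_t, n_r=n_r, seed=2, n_reps=reps
    )
    report = recovery_experiment(spec)
    print(f"design {n_p} persons x {n_t} tasks x {n_r} raters ({reps} replications)")
    print(f"{'component':>10} {'truth':>7} {'mean est':>9} {'bias':>8} {'rmse':>7}")
    for c in report.components.values():
        print(
            f"{c.name:>10} {c.truth:>7.2f} {c.mean_estimate:>9.2f} "
            f"{c.bias:>8.3f} {c.rmse:>7.3f}"
        )
    print(f"mean estimated G(2,2): {report.mean_g22:.3f}\n")

print(
    "Raw estimates are unbiased at both scales, but at the small design the\n"
    "RMSE is of the same order as the components themselves — a single small\n"
    "crossed study pins down percentages of variance only roughly."
)
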