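"""Parameter recovery from synthetic calibration targets.

Generates the calibration-target surface from known "true" parameters
(no observation noise), then recovers those parameters by constrained
optimisation starting from deliberately wrong values.  This is the test
that the calibration machinery identifies what it claims to.
"""

from ymhsim import CalibrationProblem, calibrate, default_config, generate_synthetic_targets

TRUTH = {
    "distress.onset.a18_24": 0.29,
    "services.helpseek.dis": 0.95,
    "events.selfharm.dis": 0.0070,
}
BOUNDS = {
    "distress.onset.a18_24": (0.10, 0.60),
    "services.helpseek.dis": (0.50, 1.60),
    "events.selfharm.dis": (0.003, 0.020),
}

targets = generate_synthetic_targets(TRUTH, seed=0, noise_cv=0.0)
config = default_config()
config["simulation"]["stop"] = 2024.0  # fit on the calibration window only
problem = CalibrationProblem([(p, *BOUNDS[p]) for p in TRUTH], targets, config)
result = calibrate(problem, seed=1, maxiter=12, popsize=7)

print(f"{'parameter':28s}{'true':>10s}{'recovered':>12s}{'error':>8s}")
for path, true_val in TRUTH.items():
    fit = result.parameters[path]
    print(f"{path:28s}{true_val:10.4f}{fit:12.4f}{100 * (fit - true_val) / true_val:7.1f}%")
print(f"\nfinal loss {result.loss:.2e} (weighted sum of squared relative errors)")
print("Recovery within a few percent from noise-free targets shows the\n"
      "selected rates are identifiable from the published surface.")
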