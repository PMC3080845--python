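#!/usr/bin/env python
"""Fit relaxation models to the two-timescale benchmark series.

Generates the reference stochastic process (variance fractions 0.49/0.51,
correlation times 0.4/12.9 ns, 10^6 steps at 10 ps), estimates C(t) to
100 ns and fits the two-exponential model (with the Bartlett-weighted
protocol) plus the four-exponential and stretched alternatives on the same
curve, reporting parameters and residuals.
"""

import argparse
from pathlib import Path

import pandas as pd

from popshift.kinetics import autocorrelation, fit_relaxation
from popshift.synthetic import sample_langevin_series


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/kinetics"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    series = sample_langevin_series([0.4, 12.9], [0.49, 0.51], dt=0.01, n_steps=1_000_000, seed=args.seed)
    corr = autocorrelation(series, 100.0)
    corr.to_csv(args.out / "autocorrelation.tsv", sep="\t", index=False)

    rows = []
    fit2 = fit_relaxation(corr, "exp2", seed=args.seed, lag_spacing="log", weighting="bartlett")
    print(
        f"two-exponential: a = {fit2.amplitudes[0]:.3f}, "
        f"tau_fast = {fit2.times[0]:.3f} ns, tau_slow = {fit2.times[1]:.2f} ns "
        f"(generated from 0.49 / 0.4 ns / 12.9 ns)"
    )
    rows.append({"model": "exp2", "residual_rms": fit2.residual_rms,
                 "amplitudes": list(fit2.amplitudes), "times_ns": list(fit2.times), "beta": None})

    for form in ("exp4", "stretched"):
        fit = fit_relaxation(corr, form, seed=args.seed, lag_spacing="log")
        rows.append({"model": form, "residual_rms": fit.residual_rms,
                     "amplitudes": list(fit.amplitudes), "times_ns": list(fit.times), "beta": fit.beta})
        print(f"{form}: residual rms {fit.residual_rms:.2e}")

    pd.DataFrame(rows).to_csv(args.out / "fits.tsv", sep="\t", index=False)
    print(f"outputs written to {args.out}")


if __name__ == "__main__":
    main()
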