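#!/usr/bin/env python
"""Residual-dipolar-coupling validation harness on synthetic ground truth.

Builds a two-substate chain ensemble, generates synthetic couplings from a
known alignment tensor (clean and at 10% noise), refits the tensor, and
traces the average Q-factor as a function of the averaging-window size -
showing how agreement improves once sampling covers both substates.
"""

import argparse
from pathlib import Path

import numpy as np

from popshift.ensemble import ConformerEnsemble
from popshift.rdc import convergence_curve, fit_alignment_tensor_svd
from popshift.synthetic import make_synthetic_rdc

TENSOR = np.array([4.0, -2.5, 1.2, 0.8, -3.1])


def chain_ensemble(seed):
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 5.0, size=(40, 3))
    shift = rng.normal(0.0, 1.2, size=(40, 3))
    state_a = base[None] + rng.normal(0, 0.15, (32, 40, 3))
    state_b = (base + shift)[None] + rng.normal(0, 0.15, (32, 40, 3))
    frames = np.concatenate([state_a, state_b])
    n = frames.shape[1]
    return ConformerEnsemble(
        atom_id=np.arange(1, n + 1), res_id=np.arange(1, n + 1),
        atom_name=np.full(n, "CA"), element=np.full(n, "C"), frames=frames,
    )


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/rdc"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ens = chain_ensemble(args.seed)
    clean = make_synthetic_rdc(ens, TENSOR, noise_sd=0.0)
    fit = fit_alignment_tensor_svd(ens, clean, "synthetic")
    print(f"noise-free refit: Q = {fit.q_value:.2e}, "
          f"max tensor error = {np.max(np.abs(fit.tensor - TENSOR)):.2e}")

    rms = float(np.sqrt(np.mean(clean.records["D_exp"] ** 2)))
    noisy = make_synthetic_rdc(ens, TENSOR, noise_sd=0.1 * rms, seed=args.seed + 1)
    noisy.to_tsv(args.out / "synthetic_rdc.tsv")
    fit_noisy = fit_alignment_tensor_svd(ens, noisy, "synthetic")
    print(f"10% noise refit:  Q = {fit_noisy.q_value:.3f} (expected ~0.1)")

    curve = convergence_curve(ens, clean, [8, 16, 32, 64])
    curve.to_csv(args.out / "convergence.tsv", sep="\t", index=False)
    print("window-size convergence of average Q (couplings from the full average):")
    for row in curve.itertuples(index=False):
        print(f"  window {row.window:>3} frames: Q_av = {row.q_av:.4f}")
    print(f"outputs written to {args.out}")


if __name__ == "__main__":
    main()
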