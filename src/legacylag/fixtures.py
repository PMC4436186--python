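"""Synthetic fixture generation.

These fixtures emulate the external inputs a real application would supply:
a tabulated travel-time density such as a groundwater-model export, a noisy
observed outlet-concentration record, and a parameter file sitting exactly
on the sigma = lambda degenerate manifold of the closed forms.  All outputs
are plain text and byte-identical under a fixed seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .config import walnut_creek
from .outlet_response import outlet_trajectory
from .travel_time import TabulatedTTD, write_ttd_table

__all__ = ["make_fixtures"]

#: observation record length (years) of the synthetic monitored series
N_OBSERVED_YEARS = 13
#: standard deviation of the synthetic observation noise (mg/L)
OBS_NOISE_SD = 0.3


def make_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Write the synthetic fixture set; returns {name: path}.

    * ``ttd_table`` -- exponential density with mean 21.6 y discretized on
      tau in [0, 150] y at 0.5 y spacing (a stand-in for a flow-model
      export; trapezoid mass within 1e-3 of 1 before renormalization).
    * ``observed`` -- a synthetic 13-year "monitored" outlet record: the
      full-legacy (S3) trajectory for the packaged Walnut Creek config at
      the mid denitrification rate, plus seeded Gaussian noise
      (sd 0.3 mg/L), floored at zero.
    * ``degenerate_config`` -- a config with 1 + mu*k exactly equal to
      lambda*mu (mu=20 y, k=0.11, lambda=0.16: 1/mu + k = lambda), which
      exercises the analytic engine's sigma = lambda limit path.
    """
    if seed is None:
        raise ValueError("a seed is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    # (a) tabulated TTD discretizing an exponential, mean 21.6 y
    mu = 21.6
    taus = np.arange(0.0, 150.0 + 0.25, 0.5)
    dens = np.exp(-taus / mu) / mu
    ttd_path = out_dir / "ttd_exponential_mu21.6_synthetic.tsv"
    write_ttd_table(TabulatedTTD(taus, dens), ttd_path)
    paths["ttd_table"] = ttd_path

    # (b) synthetic observed outlet series (model output + noise)
    cfg = walnut_creek()
    years = np.arange(1.0, N_OBSERVED_YEARS + 1.0)
    traj = outlet_trajectory(years, cfg.model("mid"), mode="S3")
    noisy = np.maximum(traj.values + rng.normal(0.0, OBS_NOISE_SD, years.size), 0.0)
    obs_path = out_dir / "observed_outlet_synthetic.tsv"
    with open(obs_path, "w") as fh:
        fh.write("year\tconcentration_mg_per_L\n")
        for y, v in zip(years, noisy):
            fh.write(f"{y:.1f}\t{v:.6f}\n")
    paths["observed"] = obs_path

    # (c) degenerate-manifold config: 1/mu + k == lambda exactly
    degen = {
        "source_zone": {
            "mson0_kg_per_ha": 100.0,
            "cs0_mg_per_L": 15.0,
            "lambda_per_y": 0.16,
            "recharge_mm_per_y": 129.5,
            "saturation": 0.5,
            "porosity": 0.3,
            "depth_m": 1.0,
        },
        "ttd": {"kind": "exponential", "mu_years": 20.0},
        "denitrification": {"k_per_y": 0.11},
        "scenario": {"pattern": "random", "p": 0.5},
    }
    degen_path = out_dir / "degenerate_sigma_eq_lambda.yaml"
    with open(degen_path, "w") as fh:
        fh.write("# sigma = 1/mu + k equals lambda exactly: closed-form c1 diverges\n")
        yaml.safe_dump(degen, fh, sort_keys=False)
    paths["degenerate_config"] = degen_path
    return paths
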