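"""Reference simulation experiments.

Two canned experiments exercise the whole estimation chain under the
package's standard synthetic conditions (six-region truth with common
V_ND = 2.35, gamma-variate-plus-washout input, 90-min frame schedule,
frame-wise Gaussian noise at 5% of each TAC's mean activity):

* :func:`bpnd_recovery_bias` — Monte Carlo accuracy of BP_ND: the mean over
  regions of the absolute relative bias (%) of the mean estimate.
* :func:`grid_vs_optimizer_vnd_diff` — agreement between the two SIME
  estimation routes: mean relative difference (%) in V_ND between the
  profile grid search and the bounded optimizer on the same noisy datasets.

Both accept a single master seed from which every random stream is derived.
"""

from __future__ import annotations

import numpy as np

from .frames import make_frame_schedule
from .kinetics import model_tac
from .models import SIMEModel
from .simulate import (
    NoiseProfile,
    RecoveryStats,
    add_noise,
    monte_carlo_recovery,
    reference_truth,
    synth_input,
)

__all__ = ["bpnd_recovery_bias", "grid_vs_optimizer_vnd_diff"]

_NOISE_LEVEL = 0.05
_SCHEDULE = "mmr_90"


def _conditions():
    schedule = make_frame_schedule(_SCHEDULE)
    input_function = synth_input(t_end_min=schedule.total_end_min + 5.0)
    truth = reference_truth()
    profile = NoiseProfile.flat(_NOISE_LEVEL, schedule, list(truth))
    return truth, input_function, schedule, profile


def bpnd_recovery_bias(
    seed: int = 1, n_reps: int = 200
) -> tuple[float, RecoveryStats]:
    """Mean |relative bias| (%) of BP_ND across the six regions.

    Runs the SIME Monte Carlo recovery under the standard conditions and
    averages ``100 * |mean(BP_ND) - true| / true`` over regions.  Returns
    the scalar plus the full :class:`RecoveryStats`.
    """
    truth, input_function, schedule, profile = _conditions()
    stats = monte_carlo_recovery(
        truth, input_function, schedule, profile, n_reps=n_reps, seed=seed
    )
    return stats.mean_abs_bias("BP_ND"), stats


def grid_vs_optimizer_vnd_diff(
    seed: int = 1,
    n_datasets: int = 20,
    grid_start: float = 0.5,
    grid_stop: float = 6.0,
    grid_step: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Mean relative V_ND difference (%) between grid-search and optimizer SIME.

    Generates ``n_datasets`` noisy six-region datasets (dataset d uses the
    substream (seed, d)), estimates V_ND with both routes on each, and
    returns the mean of ``100 * |V_ND_grid - V_ND_opt| / V_ND_opt`` along
    with the per-dataset values.
    """
    truth, input_function, schedule, profile = _conditions()
    clean = [
        model_tac(rates, input_function, schedule, region=name)
        for name, rates in truth.items()
    ]
    grid = np.arange(grid_start, grid_stop + 1e-9, grid_step)
    diffs = np.empty(n_datasets)
    for d in range(n_datasets):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10_000 + d]))
        noisy = [add_noise(tac, profile, rng) for tac in clean]
        model = SIMEModel(noisy, input_function)
        opt = model.fit(method="optimizer", n_starts=2,
                        seed=(int(seed) * 1000 + d) % 2**31)
        gs = model.fit(method="grid", grid=grid)
        diffs[d] = 100.0 * abs(gs.V_ND_common - opt.V_ND_common) / opt.V_ND_common
    return float(np.mean(diffs)), diffs
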