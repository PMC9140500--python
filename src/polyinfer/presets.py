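"""Named experiment presets encoding the published parameter settings.

fig3: periodic environment (pi_ab = pi_ba = 0.95).
fig4: sticky-B environment (pi_ab = 0.85, pi_ba = 0.25).
fig5: 3x3 ratio sweep, 50 perturbations x 50 time units.
fig6: piecewise schedule, periodic then sticky-B (pi_ab = 0.85,
      pi_ba = 0.05) from the boundary on.
fig7: B-Program regulation with 100 T monomers (calibration).
"""

from __future__ import annotations

import copy

PRESETS: dict[str, dict] = {
    "fig3": {
        "environment": {"pi_ab": 0.95, "pi_ba": 0.95},
        "analysis": {"track_polymers": True},
    },
    "fig4": {
        "environment": {"pi_ab": 0.85, "pi_ba": 0.25},
        "analysis": {"track_polymers": True},
    },
    "fig5": {
        "environment": {"pi_ab": 0.95, "pi_ba": 0.95},
        "analysis": {"replicates": 20, "sample_every": 5.0},
    },
    "fig6": {
        "environment": {
            "segments": [
                {"pi_ab": 0.95, "pi_ba": 0.95, "n_perturbations": 10},
                {"pi_ab": 0.85, "pi_ba": 0.05, "n_perturbations": 40},
            ],
            "seed": 0,
        },
        "analysis": {"track_polymers": True},
    },
    "fig7": {
        "environment": {"pi_ab": 0.95, "pi_ba": 0.95, "n_perturbations": 12},
        "circuit": {"n_t": 100, "program_mode": True},
        "analysis": {"track_polymers": True},
    },
}


def preset_config(name: str) -> dict:
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return copy.deepcopy(PRESETS[name])
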