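"""Named genotype presets for the simulator and the acquisition schedule.

``wt``     — 10-min commitment lag, resection halts after INT1 (homology
             search curtails it), 5-min burst spacing, mobility recovers
             ~30 min after cleavage.
``yku70``  — no commitment lag, resection continues through INT2 at the fast
             phase speed, 2-min burst spacing, earlier mobility recovery.
``uncut``  — no galactose induction: no cleavage, foci persist.
"""

from __future__ import annotations

from dataclasses import replace

from .synthetic_microscopy import AcquisitionParams, RenderParams, ResectionScenario

PRESET_NAMES = ("wt", "yku70", "uncut")


def scenario_preset(name: str) -> ResectionScenario:
    base = ResectionScenario()
    if name == "wt":
        return base
    if name == "yku70":
        return replace(base, commitment_lag_min=0.0, fast_phase_enabled=True,
                       recovery_time_min=18.0)
    if name == "uncut":
        return replace(base, p_cut=0.0)
    raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def acquisition_preset(name: str, **overrides) -> AcquisitionParams:
    base = dict(burst_interval_min=2.0 if name == "yku70" else 5.0)
    base.update(overrides)
    return AcquisitionParams(**base)


def render_preset(name: str = "default", **overrides) -> RenderParams:
    return RenderParams(**overrides)
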