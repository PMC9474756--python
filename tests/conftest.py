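"""Shared fixtures: reduced phantoms and (expensive) end-to-end runs.

The end-to-end fixtures are session-scoped so the full correction pipeline
runs once and its results feed several independent assertions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tbmoco as tb
from tbmoco.correction import aff_seq, nmc, syn_seq
from tbmoco.evaluation import alignment_curves
from tbmoco.kinetics import fit_tac
from tbmoco.phantom import (
    MotionEvent,
    OrganSpec,
    PhantomSpec,
    generate,
    small_test_spec,
)
from tbmoco.registration import AffineRegConfig, SynConfig

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def tiny_spec(seed: int = 0, motion=None, noise_level: float = 0.04) -> PhantomSpec:
    """Minimal phantom (20x20x40 voxels, 8 one-minute frames) for tests that
    only need structure + motion, not anatomical detail."""
    grid = tb.VoxelGrid.centered((20, 20, 40), (10.0, 10.0, 10.0))
    schedule = tb.build_schedule([(60, 8)])
    from tbmoco.kinetics import KineticParams

    body = OrganSpec("body", (0.0, 0.0, 0.0), (80.0, 75.0, 170.0), KineticParams(0.05, 0.4, 0.01))
    organs = (
        OrganSpec("hot_organ", (20.0, 10.0, 50.0), (35.0, 30.0, 40.0), KineticParams(0.4, 0.5, 0.06)),
        OrganSpec("cold_organ", (-25.0, -15.0, -60.0), (28.0, 28.0, 45.0), KineticParams(0.03, 0.3, 0.02)),
    )
    if motion is None:
        motion = (MotionEvent(6, "shift", 9.0, direction=(0.5, 0.3, 0.8)),)
    return PhantomSpec(
        grid=grid,
        schedule=schedule,
        body=body,
        organs=organs,
        motion=tuple(motion),
        noise_level=noise_level,
        seed=seed,
        reference_cut_s=300.0,
    )


FAST_SYN = SynConfig(iterations=(30, 20, 12), sigma_total_vox=0.0)
FAST_AFFINE = AffineRegConfig(levels=2, shrink=(4, 2), sigmas_vox=(2.0, 1.0))


def _roi_ki(corrected, truth, schedule):
    """Reference-position organ-ROI Ki estimates from a corrected series."""
    out = {}
    for organ, mask in truth.organ_masks.items():
        if organ == "aorta":
            continue
        tac = corrected.data[:, mask].mean(axis=1).astype(float)
        fit = fit_tac(tac, truth.cp, schedule)
        out[organ] = fit.params.Ki if fit.params is not None else np.nan
    return out


@pytest.fixture(scope="session")
def small_motion_spec():
    return small_test_spec(seed=7)


@pytest.fixture(scope="session")
def motion_run(small_motion_spec):
    """One full small-phantom run: NMC, SyN-seq and Aff-seq corrections with
    alignment curves and reference-position organ-ROI Ki fits."""
    spec = small_motion_spec
    dyn, truth = generate(spec)
    ref = tb.reference_frame_index(spec.schedule, spec.reference_cut_s)
    runs = {}
    for label, result in (
        ("NMC", nmc(dyn, ref)),
        ("SyN-seq", syn_seq(dyn, ref, FAST_SYN)),
        ("Aff-seq", aff_seq(dyn, ref, FAST_AFFINE)),
    ):
        curves = alignment_curves(result.corrected, ref)
        runs[label] = {
            "result": result,
            "curves": curves,
            "organ_ki": _roi_ki(result.corrected, truth, spec.schedule),
        }
    return {"spec": spec, "dynamic": dyn, "truth": truth, "ref": ref, "runs": runs}


@pytest.fixture(scope="session")
def cohort_runs():
    """Multi-seed cohort (subject-to-subject kinetic variation + random
    motion) corrected with SyN-seq, for inter-subject CV comparisons."""
    seeds = [11, 12, 13, 14, 15]
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        spec = small_test_spec(seed=seed)
        # per-subject kinetic variation: +/-10% lognormal jitter per organ
        organs = []
        for organ in spec.organs:
            if organ.blood or organ.params is None:
                organs.append(organ)
                continue
            f = np.exp(rng.normal(0.0, 0.1, size=3))
            from tbmoco.kinetics import KineticParams

            organs.append(
                replace(
                    organ,
                    params=KineticParams(
                        organ.params.K1 * f[0], organ.params.k2 * f[1], organ.params.k3 * f[2]
                    ),
                )
            )
        direction = rng.normal(size=3)
        magnitude = float(rng.uniform(7.0, 12.0))
        spec = replace(
            spec,
            organs=tuple(organs),
            motion=(
                MotionEvent(12, "shift", magnitude, direction=tuple(direction)),
                MotionEvent(14, "smooth-warp", 6.0, wavelength_mm=70.0),
            ),
        )
        dyn, truth = generate(spec)
        ref = tb.reference_frame_index(spec.schedule, spec.reference_cut_s)
        corrected = syn_seq(dyn, ref, FAST_SYN)
        rows.append(
            {
                "seed": seed,
                "truth": truth,
                "schedule": spec.schedule,
                "ki": {
                    "NMC": _roi_ki(dyn, truth, spec.schedule),
                    "SyN-seq": _roi_ki(corrected.corrected, truth, spec.schedule),
                },
            }
        )
    return rows
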