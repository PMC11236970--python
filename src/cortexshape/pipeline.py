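"""Configuration, cohort synthesis and end-to-end orchestration.

``run_timelapse_analysis`` chains contour extraction, shape metrics,
spectral / autocorrelation analysis and cortex thickness over a cohort
of two-channel timelapse stacks, producing a per-liposome summary table
with per-condition statistics; failures and size-gate exclusions are
recorded per liposome, and the run is deterministic given the config
seed.

``synthesize_cohort`` builds ground-truth cohorts in three regimes of
cortex architecture:

- ``arp23`` (branched): near-isotropic cortex, low actin polarity, small
  membrane strain, bending/elasticity-dominated spectrum (alpha ~ 4),
  low-mode (ellipsoidal) deformation, large deformation size;
- ``mdia1`` (linear): polarized aster-forming cortex, higher polarity
  but small strain, tension-dominated spectrum (alpha ~ 2), high-mode
  deformation, small deformation size;
- ``mixed`` (branched + linear): high polarity and the largest membrane
  strain, elasticity-dominated spectrum, intermediate deformation size.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from cortexshape import contour_shape, cortex_thickness, spectral_analysis
from cortexshape import synthetic_scenes as scenes

log = logging.getLogger("cortexshape")

EXIT_OK, EXIT_FATAL, EXIT_PARTIAL = 0, 1, 2


@dataclass
class AnalysisConfig:
    """Pipeline configuration.

    Defaults mirror the imaging conditions of the experiments this
    pipeline is built for: 0.0938 um pixels, 6 s frame intervals, 2 min
    observation windows, PSF SD 0.119 um, and the cohort inclusion rule
    of mean radius >= 17.5 um.
    """

    pixel_size_um: float = scenes.DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = scenes.DEFAULT_FRAME_INTERVAL_S
    membrane_channel: str = "membrane"
    actin_channel: str = "actin"
    activation_frame: int | None = None
    size_gate_um: float = contour_shape.DEFAULT_SIZE_GATE_UM
    psf_sigma_um: float = scenes.DEFAULT_PSF_SIGMA_UM
    n_contour_vertices: int = 360
    spectrum_frames: int = 20       # post-activation frames averaged
    # scaling-exponent fit band: contour-extraction noise sets a flat
    # power floor at high q, so the fit covers the resolvable modes
    spectrum_q_range: tuple = (2, 10)
    polarity_band_px: float = 3.0
    curvature_separation: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.membrane_channel == self.actin_channel:
            raise ValueError("membrane and actin channels must be distinct")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# condition presets and cohort synthesis
# ---------------------------------------------------------------------------

@dataclass
class ConditionPreset:
    """Ground-truth regime of one cortex-architecture condition."""

    name: str
    ramp_modes: dict[int, float]      # deterministic deformation mode weights
    strain_target: float              # eps_memb at the final frame
    polarity_target: float
    kappa: float                      # fluctuation spectrum weights
    gamma: float
    fluctuation_rms_um: float = 0.04
    alpha_nominal: float = 4.0        # regime label for rank-order checks


PRESETS: dict[str, ConditionPreset] = {
    "arp23": ConditionPreset(
        name="arp23", ramp_modes={2: 1.0, 3: 0.5},
        strain_target=0.006, polarity_target=0.10,
        kappa=1.0, gamma=0.0, alpha_nominal=4.0,
    ),
    "mdia1": ConditionPreset(
        name="mdia1", ramp_modes={5: 1.0, 6: 0.7, 8: 0.5},
        strain_target=0.005, polarity_target=0.20,
        kappa=0.0, gamma=1.0, alpha_nominal=2.0,
    ),
    "mixed": ConditionPreset(
        name="mixed", ramp_modes={3: 1.0, 4: 0.8, 5: 0.6},
        strain_target=0.018, polarity_target=0.24,
        kappa=1.0, gamma=0.0, alpha_nominal=4.0,
    ),
}


def _ramp_amplitudes(preset: ConditionPreset, radius_um: float,
                     rng: np.random.Generator) -> dict[int, complex]:
    """Solve the mode-amplitude scale giving the preset's final strain."""
    phases = {q: np.exp(1j * rng.uniform(0, 2 * np.pi))
              for q in preset.ramp_modes}

    def strain_at(scale):
        amps = {q: scale * w * radius_um * phases[q]
                for q, w in preset.ramp_modes.items()}
        c = scenes.contour_from_modes(radius_um, amps)
        return contour_shape.shape_metrics(c).membrane_strain

    if preset.strain_target <= 0:
        return {q: 0j for q in preset.ramp_modes}
    scale = brentq(lambda s: strain_at(s) - preset.strain_target, 0.0, 0.2,
                   xtol=1e-10)
    return {q: scale * w * radius_um * phases[q]
            for q, w in preset.ramp_modes.items()}


@dataclass
class SyntheticLiposome:
    liposome_id: str
    condition: str
    membrane_stack: np.ndarray
    actin_stack: np.ndarray
    truth: dict


def synthesize_cohort(
    condition_presets: list[str],
    n: int,
    seed: int = 0,
    pixel_size_um: float = scenes.DEFAULT_PIXEL_SIZE_UM,
    n_frames: int = 21,
    radius_range_um: tuple[float, float] = (18.0, 24.0),
    cortex_thickness_um: float = 0.29,
    psf_sigma_um: float = scenes.DEFAULT_PSF_SIGMA_UM,
    noise: bool = True,
    ramp_frames: int | None = None,
) -> list[SyntheticLiposome]:
    """Generate per-condition two-channel timelapse scenes with truths.

    Each liposome combines (i) a deterministic deformation ramp whose
    final membrane strain equals the preset target, (ii) per-frame
    fluctuation modes drawn from the preset's spectrum regime, and
    (iii) a polarized cortical intensity with the preset polarity.  The
    truth dict records the generating values plus geometry-level strain
    computed from the true contours.
    """
    unknown = [p for p in condition_presets if p not in PRESETS]
    if unknown:
        raise ValueError(f"unknown presets {unknown}; available: "
                         f"{sorted(PRESETS)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[SyntheticLiposome] = []
    for cond in condition_presets:
        preset = PRESETS[cond]
        for i in range(n):
            lip_seed = int(rng.integers(0, 2**31 - 1))
            lip_rng = np.random.default_rng(lip_seed)
            radius = float(lip_rng.uniform(*radius_range_um))
            ramp_amps = _ramp_amplitudes(preset, radius, lip_rng)
            _, fluct_truth = scenes.sample_contour_series(
                radius, kappa=preset.kappa, gamma=preset.gamma,
                n_modes=10, n_frames=n_frames,
                seed=int(lip_rng.integers(0, 2**31 - 1)),
                amplitude_rms_um=preset.fluctuation_rms_um,
            )
            nf_ramp = n_frames - 1 if ramp_frames is None else ramp_frames
            memb_frames, act_frames = [], []
            true_contours = []
            polarity_real = np.nan
            for k in range(n_frames):
                ramp = min(1.0, k / max(nf_ramp, 1))
                amps = {q: ramp * a for q, a in ramp_amps.items()}
                # superpose per-frame fluctuation modes onto the ramp
                for q, a in fluct_truth.mode_amplitude_series[k].items():
                    amps[q] = amps.get(q, 0j) + a
                contour = scenes.contour_from_modes(radius, amps)
                true_contours.append(contour)
                pol_I, polarity_real = scenes.make_polarized_cortex(
                    contour, preset.polarity_target, profile="vonmises")
                memb, act, _ = scenes.render_two_channel_frame(
                    contour, cortex_thickness_um, psf_sigma_um,
                    noise_model=scenes.PoissonGaussianNoise() if noise else None,
                    pixel_size_um=pixel_size_um,
                    seed=int(lip_rng.integers(0, 2**31 - 1)),
                )
                act = _modulate_cortex(act, contour, pol_I, pixel_size_um)
                memb_frames.append(memb)
                act_frames.append(act)
            shape = tuple(np.max([f.shape for f in memb_frames], axis=0))
            memb_stack = _pad_stack(memb_frames, shape)
            act_stack = _pad_stack(act_frames, shape)
            truth_strain = [
                contour_shape.shape_metrics(c).membrane_strain
                for c in true_contours
            ]
            theta_u = [contour_shape.radial_decomposition(c)[2]
                       for c in true_contours]
            truth = dict(
                condition=cond, radius_um=radius, seed=lip_seed,
                strain_series=truth_strain,
                max_strain=float(np.max(truth_strain)),
                polarity=float(polarity_real),
                alpha_nominal=preset.alpha_nominal,
                theta_c_deg=float(
                    spectral_analysis.angular_autocorrelation_size(
                        np.asarray(theta_u)).theta_c_deg),
                cortex_thickness_um=cortex_thickness_um,
                psf_sigma_um=psf_sigma_um,
            )
            out.append(SyntheticLiposome(
                liposome_id=f"{cond}_{i:02d}", condition=cond,
                membrane_stack=memb_stack, actin_stack=act_stack,
                truth=truth,
            ))
    return out


def _modulate_cortex(actin_image, contour, vertex_intensity, pixel_size_um):
    """Scale the rendered actin channel azimuthally by the polarity profile.

    The whole radial profile of each ray is scaled by the same weight,
    so per-ray intensity ratios (and hence the thickness geometry) are
    preserved while the membrane-sampled intensity follows the polarity
    profile exactly.
    """
    v = contour.vertices - contour.center_of_mass
    ang = np.arctan2(v[:, 1], v[:, 0])
    order = np.argsort(ang)
    H, W = actin_image.shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    rows, cols = np.mgrid[0:H, 0:W]
    theta_pix = np.arctan2((rows - cy), (cols - cx))
    from cortexshape._util import interp_periodic

    weight = interp_periodic(theta_pix.ravel(), ang[order],
                             vertex_intensity[order]).reshape(H, W)
    weight = weight / max(vertex_intensity.max(), 1e-12)
    return actin_image * weight


def _pad_stack(frames, shape):
    stack = np.zeros((len(frames), *shape), dtype=np.float32)
    for k, f in enumerate(frames):
        r0 = (shape[0] - f.shape[0]) // 2
        c0 = (shape[1] - f.shape[1]) // 2
        stack[k, r0:r0 + f.shape[0], c0:c0 + f.shape[1]] = f
    return stack


# ---------------------------------------------------------------------------
# end-to-end analysis
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    per_liposome: pd.DataFrame
    per_condition: pd.DataFrame
    exclusions: list[dict]
    config_hash: str
    exit_code: int = EXIT_OK


def analyze_liposome(
    membrane_stack: np.ndarray,
    actin_stack: np.ndarray,
    config: AnalysisConfig,
) -> dict:
    """Full single-liposome analysis: contours -> shape metrics ->
    spectrum / ACF -> thickness."""
    n_frames = membrane_stack.shape[0]
    contours = [
        contour_shape.extract_contour(
            membrane_stack[k], config.pixel_size_um,
            n_vertices=config.n_contour_vertices, frame=k)
        for k in range(n_frames)
    ]
    ts = contour_shape.metric_timeseries(
        contours, actin_stack, config.pixel_size_um,
        band_px=config.polarity_band_px,
        activation_frame=config.activation_frame,
    )
    u_series = np.asarray([
        contour_shape.radial_decomposition(c)[2] for c in contours
    ])
    start = config.activation_frame or 0
    stop = min(n_frames, start + config.spectrum_frames)
    spec = spectral_analysis.deformation_power_spectrum(
        u_series, frames=slice(start, stop))
    alpha = spectral_analysis.fit_scaling_exponent(
        spec, tuple(config.spectrum_q_range))
    size = spectral_analysis.angular_autocorrelation_size(u_series[start:stop])
    try:
        thick = cortex_thickness.thickness_from_images(
            contours[0], membrane_stack[0], actin_stack[0],
            config.pixel_size_um, config.psf_sigma_um)
        h_um = thick.h_um
    except cortex_thickness.ThicknessError as exc:
        log.warning("thickness estimation failed: %s", exc)
        h_um = np.nan
    return dict(
        eps_memb_max=ts.max_membrane_strain,
        P_act_max=ts.max_polarity,
        alpha=alpha,
        theta_c_deg=size.theta_c_deg,
        h_um=h_um,
        R_mean_um=ts.initial_radius_um,
        contours=contours,
        timeseries=ts.table,
        spectrum=spec,
    )


def run_timelapse_analysis(
    config: AnalysisConfig,
    liposomes: list[SyntheticLiposome] | list[dict],
    out_dir: str | Path | None = None,
) -> CohortSummary:
    """Run the per-liposome pipeline over a cohort and summarize.

    ``liposomes`` entries provide ``liposome_id``, ``condition``,
    ``membrane_stack`` and ``actin_stack`` (attributes or keys).  Stage
    failures and size-gate exclusions are recorded and the pipeline
    continues; the exit code is 0 (all analyzed), 2 (some failed) or 1
    (all failed).
    """
    rows, exclusions = [], []
    for lip in liposomes:
        get = (lambda k, o=lip: getattr(o, k)) if not isinstance(lip, dict) \
            else (lambda k, o=lip: o[k])
        lip_id, cond = get("liposome_id"), get("condition")
        try:
            res = analyze_liposome(get("membrane_stack"), get("actin_stack"),
                                   config)
        except Exception as exc:  # pipeline continues on remaining liposomes
            log.warning("liposome %s failed: %s", lip_id, exc)
            exclusions.append(dict(liposome_id=lip_id, condition=cond,
                                   reason="contour_failure", detail=str(exc)))
            continue
        if not contour_shape.passes_size_gate(res["R_mean_um"],
                                              config.size_gate_um):
            exclusions.append(dict(liposome_id=lip_id, condition=cond,
                                   reason="size_gate",
                                   detail=f"R = {res['R_mean_um']:.1f} um"))
            continue
        rows.append(dict(
            liposome_id=lip_id, condition=cond,
            eps_memb_max=res["eps_memb_max"], P_act_max=res["P_act_max"],
            alpha=res["alpha"], theta_c_deg=res["theta_c_deg"],
            h_um=res["h_um"], R_mean_um=res["R_mean_um"],
        ))
    per_liposome = pd.DataFrame(rows)
    if len(per_liposome):
        agg = per_liposome.groupby("condition").agg(
            n=("liposome_id", "count"),
            **{f"{m}_{s}": (m, s)
               for m in ("eps_memb_max", "P_act_max", "alpha", "theta_c_deg",
                         "h_um")
               for s in ("mean", "std", "median")},
        ).reset_index()
    else:
        agg = pd.DataFrame()
    code = EXIT_OK if not exclusions else (
        EXIT_PARTIAL if len(per_liposome) else EXIT_FATAL)
    summary = CohortSummary(per_liposome=per_liposome, per_condition=agg,
                            exclusions=exclusions,
                            config_hash=config.config_hash(),
                            exit_code=code)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tag = summary.config_hash
        per_liposome.to_csv(out_dir / f"per_liposome_{tag}.csv", index=False)
        agg.to_csv(out_dir / f"per_condition_{tag}.csv", index=False)
        (out_dir / f"exclusions_{tag}.json").write_text(
            json.dumps(exclusions, indent=1))
    return summary
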