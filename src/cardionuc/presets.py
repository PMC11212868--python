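"""Genotype / treatment presets for the trace and image generators.

Each preset encodes the printed group-level phenotypes for that condition;
values that are not group-specific fall back to the wild-type defaults.

Trace presets (peak strains in percent, compression negative):

* ``WT_rat`` / ``AdV_empty`` / ``DMSO`` — adult rat baseline: 11.4 % peak
  sarcomere compression transferring a dampened 6.6 % nuclear compression.
* ``AdV_DNKASH`` — acute LINC disruption: slightly stronger sarcomere
  contraction with slightly weaker nuclear compression (reduced systolic
  coupling, larger systolic dampening).
* ``colch`` — microtubule depolymerization: stronger/faster sarcomere
  relaxation while nuclear re-lengthening lags (larger diastolic
  hysteresis), nuclear compression proportionately increased.
* ``WT_mouse`` — adult mouse baseline; ``csDNKASH`` couples like WT.
* ``N195K`` — lamin A/C N195K mutant: more deformable nucleus, calibrated
  to a 30 % increase in integrated nuclear strain over WT_mouse;
  ``N195K_csDNKASH`` is not rescued (same strain transfer).

Image presets (enrichment = perinuclear/cytoplasmic tubulin ratio):

* wild-type cage enrichment ~2.2 with tip-biased cage; acute AdV DN-KASH
  reduces it to ~1.7 and chronic cardiac-specific DN-KASH to ~1.4 while
  elongating the nucleus (36 % higher aspect ratio, 63 % on the mutant
  background); chromatin-protrusion prevalence is 20 % for N195K, ~40 % for
  cardiac-specific lamin A/C knockout, and near wild-type levels once the
  LINC complex is disrupted.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from ._util import rng_from
from .errors import ConfigError
from .images import ImageSpec, Protrusion, Tubulin, Focus, generate_nucleus_image
from .traces import TraceParams

# ---------------------------------------------------------------------------
# trace presets
# ---------------------------------------------------------------------------

_WT_RAT = dict(
    baseline_sarcomere_length=1.80, baseline_nuclear_length=12.4,
    baseline_nuclear_width=5.6, peak_sarcomere_strain=-11.4,
    target_peak_nuclear_strain=-6.6, nuclear_time_constant=0.12,
    relaxation_time_constant=0.20, width_gain=-0.35, noise_sd=0.0,
)

_WT_MOUSE = dict(_WT_RAT, peak_sarcomere_strain=-10.5,
                 target_peak_nuclear_strain=-6.0)

TRACE_PRESETS: dict[str, dict] = {
    "WT_rat": dict(_WT_RAT),
    "AdV_empty": dict(_WT_RAT),
    "DMSO": dict(_WT_RAT),
    # stronger sarcomere contraction but weaker nuclear transfer
    "AdV_DNKASH": dict(_WT_RAT, peak_sarcomere_strain=-12.0,
                       target_peak_nuclear_strain=-6.2),
    # faster sarcomere relaxation, lagging nuclear re-lengthening
    "colch": dict(_WT_RAT, peak_sarcomere_strain=-12.5,
                  relaxation_time_constant=0.13,
                  nuclear_time_constant=0.20,
                  target_peak_nuclear_strain=-7.2),
    "WT_mouse": dict(_WT_MOUSE),
    "csDNKASH": dict(_WT_MOUSE, baseline_nuclear_length=13.5,
                     baseline_nuclear_width=4.8),
    # 1.30 x WT_mouse peak target => exactly 30% more integrated strain
    "N195K": dict(_WT_MOUSE, target_peak_nuclear_strain=-7.8),
    "N195K_csDNKASH": dict(_WT_MOUSE, target_peak_nuclear_strain=-7.8,
                           baseline_nuclear_length=14.3,
                           baseline_nuclear_width=4.5),
}

# ---------------------------------------------------------------------------
# image presets: nucleus shape, cage enrichment, protrusion prevalence
# ---------------------------------------------------------------------------

IMAGE_PRESETS: dict[str, dict] = {
    # semi_axes chosen so aspect ratios track the group means:
    # WT ~2.2; csDN-KASH +36%; N195K same as WT; combined +63%
    "WT_mouse": dict(semi_axes=(6.2, 2.8), enrichment=2.2, tip_boost=0.4,
                     prevalence=0.02, foci_mean=0.3),
    "WT_rat": dict(semi_axes=(6.2, 2.8), enrichment=2.2, tip_boost=0.4,
                   prevalence=0.02, foci_mean=0.3),
    "AdV_empty": dict(semi_axes=(6.2, 2.8), enrichment=2.2, tip_boost=0.4,
                      prevalence=0.02, foci_mean=0.3),
    "DMSO": dict(semi_axes=(6.2, 2.8), enrichment=2.2, tip_boost=0.4,
                 prevalence=0.02, foci_mean=0.3),
    "colch": dict(semi_axes=(7.2, 2.4), enrichment=1.2, tip_boost=0.0,
                  prevalence=0.02, foci_mean=0.1),
    "AdV_DNKASH": dict(semi_axes=(6.6, 2.9), enrichment=1.7, tip_boost=0.2,
                       prevalence=0.02, foci_mean=0.3),
    "csDNKASH": dict(semi_axes=(7.2, 2.4), enrichment=1.4, tip_boost=0.0,
                     prevalence=0.02, foci_mean=0.3),
    "N195K": dict(semi_axes=(6.2, 2.8), enrichment=2.2, tip_boost=0.4,
                  prevalence=0.20, foci_mean=1.5),
    "N195K_csDNKASH": dict(semi_axes=(7.9, 2.2), enrichment=1.4, tip_boost=0.0,
                           prevalence=0.03, foci_mean=0.4),
    "Lmna_cKO": dict(semi_axes=(6.2, 2.8), enrichment=2.2, tip_boost=0.4,
                     prevalence=0.40, foci_mean=2.0),
}

DEFAULT_IMAGE_NOISE_SD = 0.03


def trace_preset(name: str, **overrides) -> TraceParams:
    """Fully populated TraceParams for a genotype/treatment preset."""
    if name not in TRACE_PRESETS:
        raise ConfigError(f"unknown trace preset {name!r}")
    fields = dict(TRACE_PRESETS[name])
    fields["genotype_label"] = name
    fields.update(overrides)
    params = TraceParams(**fields)
    params.validate()
    return params


def image_preset(name: str, protrusion_present: bool = False,
                 foci: list | None = None, noise_sd: float | None = None,
                 seed: int = 0, **overrides) -> ImageSpec:
    """Fully populated ImageSpec for a genotype/treatment preset."""
    if name not in IMAGE_PRESETS:
        raise ConfigError(f"unknown image preset {name!r}")
    p = IMAGE_PRESETS[name]
    sd = DEFAULT_IMAGE_NOISE_SD if noise_sd is None else noise_sd
    spec = ImageSpec(
        nucleus_semi_axes=p["semi_axes"],
        tubulin=Tubulin(enrichment_factor=p["enrichment"],
                        tip_boost=p["tip_boost"]),
        protrusion=Protrusion(present=protrusion_present),
        foci=list(foci or []),
        noise={"model": "gaussian", "sd": sd},
        seed=seed,
    )
    for key, val in overrides.items():
        spec = replace(spec, **{key: val})
    spec.validate()
    return spec


def genotype_preset(name: str, kind: str = "trace"):
    """Preset lookup dispatching on ``kind`` ('trace' or 'image')."""
    if kind == "trace":
        return trace_preset(name)
    if kind == "image":
        return image_preset(name)
    raise ConfigError(f"unknown preset kind {kind!r}")


def preset_prevalence(name: str) -> float:
    """Ground-truth chromatin-protrusion prevalence of an image preset."""
    if name not in IMAGE_PRESETS:
        raise ConfigError(f"unknown image preset {name!r}")
    return IMAGE_PRESETS[name]["prevalence"]


def generate_image_cohort(name: str, n_images: int, seed: int = 0,
                          noise_sd: float | None = None, size_jitter: float = 0.03,
                          with_foci: bool = True):
    """Seeded cohort of nucleus images for one genotype preset.

    Protrusion presence is Bernoulli with the preset prevalence, perinuclear
    foci counts are Poisson with the preset mean, and nuclear semi-axes get
    a small multiplicative jitter.  Yields ``(channels, GroundTruth)``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    p = IMAGE_PRESETS.get(name)
    if p is None:
        raise ConfigError(f"unknown image preset {name!r}")
    rng = rng_from(seed, "image_cohort", name)
    for i in range(n_images):
        present = bool(rng.random() < p["prevalence"])
        a, b = p["semi_axes"]
        if size_jitter > 0:
            a *= float(rng.normal(1.0, size_jitter))
            b *= float(rng.normal(1.0, size_jitter))
        foci = []
        if with_foci:
            k = int(rng.poisson(p["foci_mean"]))
            for _ in range(k):
                # place foci in the 1 um perinuclear band at a random angle
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0.2, 0.8)
                ca, sa = np.cos(ang), np.sin(ang)
                scale = 1.0 / np.sqrt((ca / a) ** 2 + (sa / b) ** 2)
                foci.append(Focus(center=((scale + rad) * ca, (scale + rad) * sa)))
        spec = image_preset(
            name, protrusion_present=present, foci=foci,
            noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)),
            nucleus_semi_axes=(a, b),
        )
        yield generate_nucleus_image(spec)
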