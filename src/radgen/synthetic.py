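"""Synthetic cohort generation.

Every downstream stage (feature extraction, clustering, differential
expression, survival analysis) is exercised on phantom data with planted
structure: 3D tumor phantoms whose shape irregularity and per-channel
intensity textures differ between planted risk groups (1, 2a, 2b), a
field-strength batch label with a systematic intensity offset, a
gene x sample expression matrix with planted up/down-regulated signature
genes, and survival times with group-dependent hazards.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .image import CHANNELS, ClinicalRecord, ImageVolume, StudyCase, TumorMask, write_case

GROUPS = ("1", "2a", "2b")

#: Above roughly this irregularity the star-shaped surface can fold deeply
#: enough that the voxelized mask is no longer guaranteed 6-connected.
CONNECTIVITY_SAFE_IRREGULARITY = 0.3


@dataclasses.dataclass(frozen=True)
class TextureParams:
    """Per-channel intensity texture: Gaussian random field of given mean,
    SD and spatial correlation length (mm); an optional two-component
    mixture (weight = fraction of voxels shifted by ``bimodal_shift``)
    produces blob-like intensity clusters."""

    mean: float
    sd: float
    corr_length_mm: float = 2.0
    bimodal_weight: float = 0.0
    bimodal_shift: float = 0.0


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    group_label: str
    base_radius_mm: float
    irregularity: float
    texture_params: Mapping[str, TextureParams]
    field_strength: str = "1.5T"
    batch_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ValueError(f"group_label must be one of {GROUPS}")
        if self.base_radius_mm <= 0:
            raise ValueError("base_radius_mm must be > 0")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")
        missing = set(CHANNELS) - set(self.texture_params)
        if missing:
            raise ValueError(f"texture_params missing channels {missing}")


@dataclasses.dataclass(frozen=True)
class ExpressionSpec:
    n_genes: int = 2000
    n_up: int = 3
    n_down: int = 8
    effect_size: float = 2.0  # mean shift in SD units, aggressive vs non-aggressive
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down must be <= n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclasses.dataclass(frozen=True)
class SurvivalSpec:
    baseline_hazard: float = 0.01  # events per month in the reference group
    hazard_ratios: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"1": 1.0, "2a": 2.0, "2b": 4.0})
    censor_rate: float = 0.2
    follow_up_months: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if any(h <= 0 for h in self.hazard_ratios.values()):
            raise ValueError("hazard ratios must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.follow_up_months <= 0:
            raise ValueError("follow_up_months must be > 0")


# ---------------------------------------------------------------------------
# Phantom imaging cases
# ---------------------------------------------------------------------------

def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic (orthonormal), theta = polar, phi = azimuth."""
    if m == 0:
        return np.real(special.sph_harm_y(l, 0, theta, phi))
    y = special.sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1) ** m * np.real(y)
    return np.sqrt(2.0) * (-1) ** m * np.imag(y)


def _angular_field(theta: np.ndarray, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean angular field: truncated real spherical-harmonic
    expansion (degrees 2-6, iid standard-normal coefficients), scaled to
    unit theoretical variance."""
    field = np.zeros_like(theta)
    n_coef = 0
    for l in range(2, 7):
        for m in range(-l, l + 1):
            field += rng.standard_normal() * _real_sph_harm(l, m, theta, phi)
            n_coef += 1
    # orthonormal harmonics: sum of n_coef unit-variance terms has angular
    # variance n_coef / (4*pi)
    return field / np.sqrt(n_coef / (4.0 * np.pi))


def _grf(shape, corr_length_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    if corr_length_vox > 0:
        field = ndimage.gaussian_filter(noise, corr_length_vox)
        sd = field.std()
        if sd > 0:
            field /= sd
        return field
    return noise


def generate_phantom_case(
    spec: PhantomSpec,
    case_id: str = "case",
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    margin_mm: float = 4.0,
) -> StudyCase:
    """Generate one phantom case.

    The tumor mask is the voxelization of the star-shaped surface
    ``r(theta, phi) = R * (1 + irregularity * eta(theta, phi))`` with eta a
    smooth zero-mean spherical-harmonic field; irregularity 0 gives a
    digital sphere.  Channel intensities inside the mask follow the
    group's texture parameters plus the field-strength batch offset;
    outside the mask a low-intensity body ellipsoid surrounds the tumor
    and the corners are zero.
    """
    spacing = tuple(float(s) for s in spacing)
    if spec.base_radius_mm < min(spacing):
        raise ValueError("base_radius_mm smaller than one voxel")
    rng = np.random.default_rng(spec.seed)

    max_r = spec.base_radius_mm * (1.0 + 3.5 * spec.irregularity) + margin_mm
    half = np.array([max_r / s for s in spacing])
    shape = tuple(int(2 * np.ceil(h) + 1) for h in half)
    centers = [(n - 1) / 2.0 for n in shape]
    ax = [(np.arange(n) - c) * s for n, c, s in zip(shape, centers, spacing)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    R = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)

    if spec.irregularity == 0:
        mask = R <= spec.base_radius_mm
    else:
        # only voxels in the ambiguous radial shell need the angular field
        r_lo = spec.base_radius_mm * max(1.0 - 3.5 * spec.irregularity, 0.05)
        r_hi = spec.base_radius_mm * (1.0 + 3.5 * spec.irregularity)
        mask = R <= r_lo
        shell = (R > r_lo) & (R <= r_hi)
        xs, ys, zs, rs = X[shell], Y[shell], Z[shell], R[shell]
        theta = np.arccos(np.clip(zs / rs, -1.0, 1.0))
        phi = np.arctan2(ys, xs)
        eta = _angular_field(theta, phi, rng)
        surf = spec.base_radius_mm * np.maximum(1.0 + spec.irregularity * eta, 0.05)
        mask[shell] = rs <= surf
    if not mask.any():
        raise ValueError("degenerate spec: empty mask")

    # body ellipsoid spanning most of the grid
    body = (sum(((g / (0.95 * h * s)) ** 2 for g, h, s in zip((X, Y, Z), half, spacing)))
            <= 1.0)

    channels: dict[str, ImageVolume] = {}
    for tag in CHANNELS:
        tp = spec.texture_params[tag]
        corr_vox = tp.corr_length_mm / min(spacing)
        vol = tp.mean + tp.sd * _grf(shape, corr_vox, rng)
        if tp.bimodal_weight > 0 and tp.bimodal_shift != 0:
            blob = _grf(shape, corr_vox, rng)
            cut = np.quantile(blob[mask], 1.0 - tp.bimodal_weight)
            vol = vol + tp.bimodal_shift * (blob > cut)
        # surrounding-tissue intensity: moderately darker than tumor, as in
        # pelvic MRI where tumors border soft tissue of comparable signal
        # (a near-zero background would make 1-voxel mask perturbations
        # unrealistically destructive)
        background = 0.75 * tp.mean + 0.5 * tp.sd * rng.standard_normal(shape)
        vol = np.where(mask, vol, np.where(body, background, 0.0))
        # point-spread-function blur: MRI voxels at tissue boundaries are
        # partial-volume mixtures, so the tumor edge must not be a step
        # (a step edge creates an artificial intensity mode under 1-voxel
        # mask perturbations)
        vol = ndimage.gaussian_filter(vol, sigma=0.8)
        vol = vol + np.where(body, spec.batch_offset, 0.0)
        channels[tag] = ImageVolume(vol, spacing, channel=tag,
                                    field_strength=spec.field_strength)
    return StudyCase(case_id, channels, TumorMask(mask, spacing),
                     group_truth=spec.group_label)


#: Study conditions for the three planted risk groups.  Group 1 mimics
#: small, regular, texturally bland tumors; 2a and 2b are larger and more
#: irregular, share the elevated contrast-channel (VIBE+C) mean, and sit on
#: a monotone aggressiveness axis on ADC/b1000 (2a intermediate, 2b
#: extreme, with blob-like bimodal ADC texture) so that the aggressive
#: groups are mutually closer than either is to group 1 — the hierarchy the
#: 2+1 clustering procedure assumes.
DEFAULT_GROUP_PHANTOMS: dict[str, dict] = {
    "1": dict(
        base_radius_mm=10.0,
        irregularity=0.05,
        texture_params={
            "VIBE+C": TextureParams(100.0, 10.0),
            "ADC": TextureParams(100.0, 10.0),
            "b1000": TextureParams(100.0, 10.0),
        },
    ),
    "2a": dict(
        base_radius_mm=13.0,
        irregularity=0.15,
        texture_params={
            "VIBE+C": TextureParams(130.0, 10.0),
            "ADC": TextureParams(85.0, 10.0),
            "b1000": TextureParams(115.0, 10.0),
        },
    ),
    "2b": dict(
        base_radius_mm=15.0,
        irregularity=0.25,
        texture_params={
            "VIBE+C": TextureParams(130.0, 10.0),
            "ADC": TextureParams(70.0, 10.0, bimodal_weight=0.3, bimodal_shift=40.0),
            "b1000": TextureParams(130.0, 10.0),
        },
    ),
}

DEFAULT_BATCH_OFFSETS = {"1.5T": 0.0, "3T": 20.0}


def default_phantom_spec(group: str, seed: int, field_strength: str = "1.5T",
                         radius_jitter_mm: float = 0.0) -> PhantomSpec:
    base = DEFAULT_GROUP_PHANTOMS[group]
    return PhantomSpec(
        group_label=group,
        base_radius_mm=base["base_radius_mm"] + radius_jitter_mm,
        irregularity=base["irregularity"],
        texture_params=base["texture_params"],
        field_strength=field_strength,
        batch_offset=DEFAULT_BATCH_OFFSETS[field_strength],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Expression matrix with planted signature genes
# ---------------------------------------------------------------------------

def generate_expression(
    spec: ExpressionSpec,
    group_labels: Sequence[str],
    aggressive_groups: Sequence[str] = ("2a", "2b"),
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Gene x sample matrix with planted up/down-regulated genes.

    Planted up-genes are shifted by +effect_size (in noise-SD units) in
    samples of the aggressive groups, down-genes by -effect_size; all other
    genes are null.  Returns the matrix and the truth sets
    ``{"up": [...], "down": [...]}``.
    """
    labels = list(group_labels)
    n_samples = len(labels)
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    elif len(sample_ids) != n_samples:
        raise ValueError("one label per sample required")
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    planted = rng.choice(spec.n_genes, size=spec.n_up + spec.n_down, replace=False)
    up_idx, down_idx = planted[:spec.n_up], planted[spec.n_up:]
    aggressive = np.array([g in set(aggressive_groups) for g in labels])
    shift = spec.effect_size * spec.noise_sd
    X[np.ix_(up_idx, np.flatnonzero(aggressive))] += shift
    X[np.ix_(down_idx, np.flatnonzero(aggressive))] -= shift
    matrix = pd.DataFrame(X, index=gene_ids, columns=list(sample_ids))
    truth = {"up": [gene_ids[i] for i in sorted(up_idx)],
             "down": [gene_ids[i] for i in sorted(down_idx)]}
    return matrix, truth


# ---------------------------------------------------------------------------
# Survival times with group-dependent hazards
# ---------------------------------------------------------------------------

def generate_survival(spec: SurvivalSpec, group_labels: Sequence[str]) -> pd.DataFrame:
    """Exponential event times with hazard = baseline x HR(group) and
    independent censoring; returns columns time_months, event, group."""
    labels = list(group_labels)
    missing = set(labels) - set(spec.hazard_ratios)
    if missing:
        raise ValueError(f"hazard_ratios missing groups {missing}")
    rng = np.random.default_rng(spec.seed)
    hazards = np.array([spec.baseline_hazard * spec.hazard_ratios[g] for g in labels])
    t_event = rng.exponential(1.0 / hazards)
    censored = rng.random(len(labels)) < spec.censor_rate
    u = rng.random(len(labels))
    time = np.where(censored, np.maximum(t_event * u, 1e-9), t_event)
    event = (~censored).astype(int)
    over = time > spec.follow_up_months
    time = np.where(over, spec.follow_up_months, time)
    event = np.where(over, 0, event)
    return pd.DataFrame({"time_months": time, "event": event, "group": labels})


# ---------------------------------------------------------------------------
# Planted feature matrices (for clustering tests without imaging)
# ---------------------------------------------------------------------------

def generate_feature_matrix(
    n_cases: int = 150,
    n_features: int = 53,
    separation: float = 3.0,
    group_fractions: Mapping[str, float] | None = None,
    n_informative: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted three-group Gaussian feature matrix in z-space with the
    hierarchical structure the 2+1 procedure assumes.

    The first ``n_informative`` features are shifted by ``separation`` SD
    units in BOTH aggressive groups (2a and 2b) — the dominant aggressive-
    vs-indolent axis; the next two blocks of ``n_informative`` features are
    shifted by ``separation``/2 in 2a only and 2b only, respectively — the
    secondary subtype axis.  Remaining features are standard-normal noise.
    """
    if group_fractions is None:
        group_fractions = {"1": 0.5, "2a": 0.3, "2b": 0.2}
    rng = np.random.default_rng(seed)
    counts = {g: int(round(f * n_cases)) for g, f in group_fractions.items()}
    counts["1"] += n_cases - sum(counts.values())
    labels = [g for g, c in counts.items() for _ in range(c)]
    X = rng.standard_normal((n_cases, n_features))
    shared = slice(0, n_informative)
    sub = {"2a": slice(n_informative, 2 * n_informative),
           "2b": slice(2 * n_informative, 3 * n_informative)}
    for g in ("2a", "2b"):
        rows = [i for i, lab in enumerate(labels) if lab == g]
        X[rows, shared] += separation
        X[rows, sub[g]] += separation / 2.0
    ids = [f"case_{i:04d}" for i in range(n_cases)]
    return (pd.DataFrame(X, index=ids, columns=[f"f{j:02d}" for j in range(n_features)]),
            pd.Series(labels, index=ids, name="group"))


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticCohort:
    cases: list[StudyCase]
    manifest: pd.DataFrame  # case_id, group, field_strength, time_months, event
    expression: pd.DataFrame
    truth_genes: dict[str, list[str]]


def generate_cohort(
    n_cases: int = 150,
    group_fractions: Mapping[str, float] | None = None,
    expression_spec: ExpressionSpec | None = None,
    survival_spec: SurvivalSpec | None = None,
    seed: int = 0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    radius_jitter_sd_mm: float = 1.0,
) -> SyntheticCohort:
    """Generate a full phantom cohort: imaging cases (with alternating
    field strengths and per-strength intensity offsets), survival records
    with group-dependent hazards, and an expression matrix with planted
    signature genes in the aggressive groups."""
    if group_fractions is None:
        group_fractions = {"1": 0.5, "2a": 0.3, "2b": 0.2}
    rng = np.random.default_rng(seed)
    counts = {g: int(round(f * n_cases)) for g, f in group_fractions.items()}
    counts["1"] += n_cases - sum(counts.values())
    labels = [g for g in GROUPS for _ in range(counts.get(g, 0))]

    cases: list[StudyCase] = []
    fs_list: list[str] = []
    for i, g in enumerate(labels):
        fs = "1.5T" if i % 2 == 0 else "3T"
        jitter = float(np.clip(rng.normal(0.0, radius_jitter_sd_mm), -3.0, 3.0))
        spec = default_phantom_spec(g, seed=int(rng.integers(2 ** 31)),
                                    field_strength=fs, radius_jitter_mm=jitter)
        cases.append(generate_phantom_case(spec, case_id=f"case_{i:04d}", spacing=spacing))
        fs_list.append(fs)

    if survival_spec is None:
        survival_spec = SurvivalSpec(seed=int(rng.integers(2 ** 31)))
    surv = generate_survival(survival_spec, labels)
    manifest = pd.DataFrame({
        "case_id": [c.case_id for c in cases],
        "group": labels,
        "field_strength": fs_list,
        "time_months": surv["time_months"].to_numpy(),
        "event": surv["event"].to_numpy(),
    })

    if expression_spec is None:
        expression_spec = ExpressionSpec(seed=int(rng.integers(2 ** 31)))
    expression, truth = generate_expression(expression_spec, labels,
                                            sample_ids=[c.case_id for c in cases])
    for c, (_, row) in zip(cases, manifest.iterrows()):
        c.clinical = ClinicalRecord(survival_months=float(row["time_months"]),
                                    dss_event=int(row["event"]))
    return SyntheticCohort(cases, manifest, expression, truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write NIfTI volumes per case, a cohort manifest CSV with file paths,
    and the expression TSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case, (_, meta) in zip(cohort.cases, cohort.manifest.iterrows()):
        paths = write_case(case, out_dir / "images")
        row = dict(meta)
        for tag, p in paths.items():
            key = "mask" if tag == "mask" else tag
            row[f"path_{key}"] = str(p)
        rows.append(row)
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    cohort.expression.to_csv(out_dir / "expression.tsv", sep="\t")
    pd.Series({k: ",".join(v) for k, v in cohort.truth_genes.items()}).to_csv(
        out_dir / "truth_genes.csv", header=False)
    return manifest_path
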