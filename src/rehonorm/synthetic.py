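"""Synthetic multi-site cohort generator.

Produces healthy-control (HC) and major-depressive-disorder (MDD) cohorts
with the statistical structure the normative-modeling analysis assumes:

* 246 brain regions partitioned into 8 canonical networks (7 cortical
  networks plus subcortex), each region carrying a smooth nonlinear age
  trajectory with a sex offset;
* additive (per site x region) and multiplicative (per site x region)
  site effects following the ComBat generative model;
* two planted MDD subtypes with opposing network-level deviation shifts of
  configurable Cohen's d, plus clinical variables (HAMD-17 total,
  anxiety/somatization factor, insight item, illness duration, medication
  status) whose between-subtype effect sizes are configurable;
* optional small 4D voxel datasets with a 246-label atlas for testing the
  ReHo-extraction stage.

All generation is driven by a single integer seed and is bitwise
reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

NETWORKS = ("FPCN", "VAN", "DMN", "LN", "DAN", "SMN", "VN", "SUB")
#: transmodal networks where subtype 1 deviates negatively
TRANSMODAL = ("FPCN", "VAN", "DMN", "LN")
#: unimodal networks where subtype 1 deviates positively
UNIMODAL = ("DAN", "SMN", "VN")

N_REGIONS = 246

# Signed between-subtype Cohen's d per network (subtype 1 minus subtype 2,
# in Z-deviation units).  Magnitudes span the 0.40-1.81 range; sign encodes
# the opposing transmodal/unimodal pattern.
DEFAULT_NETWORK_EFFECTS = {
    "FPCN": -1.75,
    "VAN": -1.00,
    "DMN": -0.70,
    "LN": -0.40,
    "DAN": 0.52,
    "SMN": 1.81,
    "VN": 1.00,
    "SUB": 0.0,
}

DEFAULT_CLINICAL_EFFECTS = {
    "age_d": -0.19,            # subtype 1 younger
    "hamd_d": 0.17,            # subtype 1 more severe overall
    "anx_som_d": -0.15,        # subtype 2 more anxiety/somatization
    "insight_d": -0.25,        # subtype 1 better insight (lower item score)
    "medication_v": 0.09,      # Cramer's V for medication x subtype
    "duration_severity_r": -0.21,  # within subtype 1 only
}


@dataclass(frozen=True)
class RegionSpec:
    """One atlas region: network membership and its lifespan trajectory.

    The normative mean is quadratic in age (in decades, centered at 40 y)
    with a sex-specific intercept offset:

        f(age, sex) = intercept + slope * t + curvature * t**2
                      + sex_offset * [sex == F],   t = (age - 40) / 10
    """

    region_id: int
    network: str
    trajectory_kind: str  # "increasing" | "decreasing"
    intercept: float
    slope_per_decade: float
    curvature: float
    sex_offset: float

    def mean_reho(self, age: np.ndarray, sex_female: np.ndarray) -> np.ndarray:
        t = (np.asarray(age, dtype=float) - 40.0) / 10.0
        return (
            self.intercept
            + self.slope_per_decade * t
            + self.curvature * t**2
            + self.sex_offset * np.asarray(sex_female, dtype=float)
        )


@dataclass
class CohortConfig:
    """Generator settings; defaults mirror the study-scale cohort."""

    n_hc: int = 1011
    n_mdd: int = 1101
    n_sites: int = 22
    site_sizes: tuple[int, ...] | None = None  # sums to n_hc + n_mdd
    age_range: tuple[float, float] = (18.0, 65.0)
    sex_ratio: float = 0.60  # proportion female
    site_location_sd: float = 0.05  # ReHo units, additive per site x region
    site_scale_range: tuple[float, float] = (0.8, 1.25)
    noise_sd: float = 0.10  # ReHo units
    within_network_corr: float = 0.5  # equicorrelation of deviations in a network
    region_effect_jitter: float = 0.4  # SD of region-level pattern around network mean
    subtype_proportions: tuple[float, float] = (0.36, 0.64)
    network_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_EFFECTS)
    )
    clinical_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 0 or self.n_mdd < 0:
            raise ValueError("n_hc and n_mdd must be nonnegative")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        p1, p2 = self.subtype_proportions
        if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
            raise ValueError("subtype_proportions must lie in (0, 1)")
        if abs(p1 + p2 - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.within_network_corr < 1.0:
            raise ValueError("within_network_corr must lie in [0, 1)")
        if self.region_effect_jitter < 0:
            raise ValueError("region_effect_jitter must be nonnegative")
        if self.site_location_sd < 0:
            raise ValueError("site_location_sd must be nonnegative")
        slo, shi = self.site_scale_range
        if not (0 < slo <= shi):
            raise ValueError("site_scale_range must be positive and ordered")
        for net, d in self.network_effects.items():
            if net not in NETWORKS:
                raise ValueError(f"network_effects: unknown network {net!r}")
            if not np.isfinite(d):
                raise ValueError(f"network_effects[{net!r}] must be finite")
        if self.site_sizes is not None:
            sizes = tuple(int(s) for s in self.site_sizes)
            if len(sizes) != self.n_sites:
                raise ValueError("site_sizes must have n_sites entries")
            if sum(sizes) != self.n_hc + self.n_mdd:
                raise ValueError("site_sizes must sum to n_hc + n_mdd")
            object.__setattr__(self, "site_sizes", sizes)


def generate_region_specs(
    n_networks: int = 8, seed: int = 0, n_regions: int = N_REGIONS
) -> list[RegionSpec]:
    """Partition ``n_regions`` regions over networks and draw trajectories.

    Every network receives at least 10 regions; trajectory kinds are split
    half increasing / half decreasing.  Same seed, same output.
    """
    if not 1 <= n_networks <= len(NETWORKS):
        raise ValueError(f"n_networks must be in 1..{len(NETWORKS)}")
    networks = NETWORKS[:n_networks]
    rng = np.random.default_rng(seed)

    base = 10
    extra = n_regions - base * n_networks
    if extra < 0:
        raise ValueError("n_regions too small for 10 regions per network")
    counts = base + rng.multinomial(extra, np.full(n_networks, 1.0 / n_networks))
    assignment = np.repeat(np.arange(n_networks), counts)
    rng.shuffle(assignment)

    kinds = np.array(["increasing", "decreasing"])[
        (np.arange(n_regions) % 2 + rng.integers(0, 2)) % 2
    ]
    rng.shuffle(kinds)

    specs: list[RegionSpec] = []
    for i in range(n_regions):
        kind = str(kinds[i])
        sign = 1.0 if kind == "increasing" else -1.0
        slope = sign * rng.uniform(0.005, 0.03)
        # curvature mild and bending against the slope so trajectories flatten
        curvature = -sign * rng.uniform(0.0, 0.002)
        specs.append(
            RegionSpec(
                region_id=i + 1,
                network=networks[assignment[i]],
                trajectory_kind=kind,
                intercept=float(rng.uniform(0.8, 1.2)),
                slope_per_decade=float(slope),
                curvature=float(curvature),
                sex_offset=float(rng.uniform(-0.02, 0.02)),
            )
        )
    return specs


def region_network_map(regions: list[RegionSpec]) -> pd.Series:
    """Series mapping region column name -> network."""
    return pd.Series(
        {f"region_{r.region_id:03d}": r.network for r in regions}, name="network"
    )


def _region_columns(regions: list[RegionSpec]) -> list[str]:
    return [f"region_{r.region_id:03d}" for r in regions]


def _site_effects(config: CohortConfig, n_regions: int):
    """Per site x region additive/multiplicative effects.

    Drawn from an RNG stream keyed only by the config seed so that HC and
    MDD cohorts generated from the same config share site effects (required
    for joint harmonization to be meaningful).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
    gamma = rng.normal(0.0, config.site_location_sd, (config.n_sites, n_regions))
    delta = rng.uniform(*config.site_scale_range, (config.n_sites, n_regions))
    return gamma, delta


def _site_split(config: CohortConfig, rng: np.random.Generator):
    """Split total site sizes into HC and MDD allotments (per-site HC share
    proportional to the overall HC fraction, remainders resolved greedily)."""
    total = config.n_hc + config.n_mdd
    if config.site_sizes is not None:
        sizes = np.asarray(config.site_sizes)
    else:
        sizes = np.full(config.n_sites, total // config.n_sites)
        sizes[: total % config.n_sites] += 1
    frac_hc = config.n_hc / total if total else 0.0
    hc_sizes = np.floor(sizes * frac_hc).astype(int)
    deficit = config.n_hc - hc_sizes.sum()
    order = np.argsort(-(sizes * frac_hc - hc_sizes))
    for j in range(abs(int(deficit))):
        hc_sizes[order[j % config.n_sites]] += 1 if deficit > 0 else -1
    mdd_sizes = sizes - hc_sizes
    return hc_sizes, mdd_sizes


def _demographics(
    n: int, config: CohortConfig, site_sizes: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    age = rng.uniform(*config.age_range, n)
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    site = np.repeat(np.arange(1, config.n_sites + 1), site_sizes)
    rng.shuffle(site)
    return pd.DataFrame({"age": age, "sex": sex, "site_id": site})


def generate_hc_cohort(
    config: CohortConfig, regions: list[RegionSpec]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Healthy-control cohort: ReHo = trajectory + site effects + noise."""
    n_regions = len(regions)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    hc_sizes, _ = _site_split(config, rng)
    cohort = _demographics(config.n_hc, config, hc_sizes, rng)
    cohort.insert(0, "subject_id", [f"HC{i:05d}" for i in range(1, config.n_hc + 1)])
    cohort["group"] = "HC"
    cohort["true_subtype"] = "none"

    gamma, delta = _site_effects(config, n_regions)
    sidx = cohort["site_id"].to_numpy() - 1
    female = (cohort["sex"] == "F").to_numpy()
    mu = np.column_stack(
        [r.mean_reho(cohort["age"].to_numpy(), female) for r in regions]
    )
    eps = rng.normal(0.0, config.noise_sd, (config.n_hc, n_regions))
    values = mu + gamma[sidx] + eps * delta[sidx]

    features = pd.DataFrame(
        values, columns=_region_columns(regions), index=cohort["subject_id"]
    )
    return cohort, features


def _draw_clinical(
    cohort: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Clinical variables with configured between-subtype effect sizes."""
    eff = config.clinical_effects
    n = len(cohort)
    is_s1 = (cohort["true_subtype"] == "1").to_numpy()
    sign = np.where(is_s1, 1.0, -1.0)  # +: shift toward subtype-1 mean

    def shifted(mean, sd, d, lo, hi):
        m = mean + sign * d * sd / 2.0
        a, b = (lo - m) / sd, (hi - m) / sd
        return stats.truncnorm.rvs(a, b, loc=m, scale=sd, random_state=rng)

    hamd_sd, dur_sd = 5.0, 4.5
    hamd_mean = np.full(n, 22.0) + sign * eff["hamd_d"] * hamd_sd / 2.0
    duration_mean = np.full(n, 5.0)

    # duration-severity correlation via a bivariate draw, subtype 1 only
    r = eff["duration_severity_r"]
    z = rng.standard_normal((n, 2))
    z_dur = z[:, 0]
    z_ham = np.where(is_s1, r * z_dur + np.sqrt(1 - r**2) * z[:, 1], z[:, 1])
    hamd = np.clip(hamd_mean + hamd_sd * z_ham, 0, 52)
    duration = np.clip(duration_mean + dur_sd * z_dur, 0.1, 40.0)

    anx = shifted(7.0, 3.0, eff["anx_som_d"], 0.0, 18.0)
    insight = np.clip(
        np.round(0.7 + sign * eff["insight_d"] * 0.6 / 2.0 + rng.normal(0, 0.6, n)),
        0,
        2,
    )

    # medication rates chosen so the 2x2 subtype x medication table has the
    # configured Cramer's V (phi) at the configured subtype proportions
    p1 = config.subtype_proportions[0]
    diff = eff["medication_v"] * 0.5 / np.sqrt(p1 * (1 - p1))
    base_rate = 0.55
    rate = np.where(is_s1, base_rate - diff / 2.0, base_rate + diff / 2.0)
    medicated = rng.random(n) < rate

    status = np.where(
        medicated, "medicated", np.where(rng.random(n) < 0.5, "FEDN", "recurrent")
    )

    out = cohort.copy()
    out["hamd17_total"] = hamd
    out["anxiety_somatization"] = anx
    out["insight_item"] = insight.astype(int)
    out["illness_duration"] = duration
    out["medicated"] = medicated
    out["episode_status"] = status
    return out


def _subtype_shift_matrix(
    config: CohortConfig, regions: list[RegionSpec], subtype: np.ndarray
) -> np.ndarray:
    """Planted deviation shift in Z units: subjects x regions.

    Subtype 1 is shifted by +d/2 per network effect, subtype 2 by -d/2.
    The network shift is scaled by the within-subtype SD of the
    *network-mean* deviation under the configured equicorrelation, so the
    empirical network-level Cohen's d between subtypes matches the
    configured value while region-level marginal variance stays 1.  A
    fixed per-region jitter (network-mean-centered, so network-level d is
    unchanged) makes the planted pattern region-specific, as observed
    subtype deviation maps are.
    """
    rho = config.within_network_corr
    net_sizes: dict[str, int] = {}
    for r in regions:
        net_sizes[r.network] = net_sizes.get(r.network, 0) + 1
    scale = {
        net: np.sqrt(rho + (1.0 - rho) / m) for net, m in net_sizes.items()
    }
    d_per_region = np.array(
        [
            config.network_effects.get(r.network, 0.0) * scale[r.network]
            for r in regions
        ]
    )
    if config.region_effect_jitter > 0:
        jitter_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x7177E2])
        )
        jitter = jitter_rng.normal(0.0, config.region_effect_jitter, len(regions))
        nets = np.array([r.network for r in regions])
        for net in net_sizes:
            idx = nets == net
            jitter[idx] -= jitter[idx].mean()
        d_per_region = d_per_region + jitter
    sign = np.where(subtype == "1", 0.5, -0.5)[:, None]
    return sign * d_per_region[None, :]


def _correlated_unit_noise(
    config: CohortConfig,
    regions: list[RegionSpec],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance deviations with within-network equicorrelation rho:
    z_ir = sqrt(rho) * u_{i,net(r)} + sqrt(1 - rho) * e_ir."""
    rho = config.within_network_corr
    e = rng.standard_normal((n, len(regions)))
    if rho == 0.0:
        return e
    nets = sorted({r.network for r in regions})
    u = rng.standard_normal((n, len(nets)))
    net_idx = np.array([nets.index(r.network) for r in regions])
    return np.sqrt(rho) * u[:, net_idx] + np.sqrt(1.0 - rho) * e


def generate_mdd_cohort(
    config: CohortConfig,
    regions: list[RegionSpec],
    hc_reference=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MDD cohort with two planted subtypes of opposing deviation patterns.

    The network shift is planted in Z units scaled by the region noise SD,
    so that downstream Z-deviation maps (which divide by total predictive
    SD) recover approximately the configured network Cohen's d.
    """
    n_regions = len(regions)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    _, mdd_sizes = _site_split(config, rng)
    cohort = _demographics(config.n_mdd, config, mdd_sizes, rng)
    cohort.insert(0, "subject_id", [f"MDD{i:05d}" for i in range(1, config.n_mdd + 1)])
    cohort["group"] = "MDD"
    cohort["true_subtype"] = np.where(
        rng.random(config.n_mdd) < config.subtype_proportions[0], "1", "2"
    )

    cohort = _draw_clinical(cohort, config, rng)
    # subtype age effect applied post hoc (kept inside the configured range)
    eff = config.clinical_effects
    age_sd = (config.age_range[1] - config.age_range[0]) / np.sqrt(12.0)
    sgn = np.where(cohort["true_subtype"] == "1", 1.0, -1.0)
    cohort["age"] = np.clip(
        cohort["age"] + sgn * eff["age_d"] * age_sd / 2.0, *config.age_range
    )

    gamma, delta = _site_effects(config, n_regions)
    sidx = cohort["site_id"].to_numpy() - 1
    female = (cohort["sex"] == "F").to_numpy()
    mu = np.column_stack(
        [r.mean_reho(cohort["age"].to_numpy(), female) for r in regions]
    )
    shift = _subtype_shift_matrix(config, regions, cohort["true_subtype"].to_numpy())
    eps = _correlated_unit_noise(config, regions, config.n_mdd, rng)
    values = mu + gamma[sidx] + (shift + eps) * config.noise_sd * delta[sidx]

    features = pd.DataFrame(
        values, columns=_region_columns(regions), index=cohort["subject_id"]
    )
    return cohort, features


def generate_mdd_deviations(
    config: CohortConfig, regions: list[RegionSpec]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Planted MDD Z-deviation maps, bypassing the normative-model stage.

    Z_ir ~ Normal(shift_ir, 1) with the same subtype shift structure as
    :func:`generate_mdd_cohort`.  Used to study the subtyping stage in
    isolation at exactly the planted effect sizes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    _, mdd_sizes = _site_split(config, rng)
    cohort = _demographics(config.n_mdd, config, mdd_sizes, rng)
    cohort.insert(0, "subject_id", [f"MDD{i:05d}" for i in range(1, config.n_mdd + 1)])
    cohort["group"] = "MDD"
    cohort["true_subtype"] = np.where(
        rng.random(config.n_mdd) < config.subtype_proportions[0], "1", "2"
    )
    cohort = _draw_clinical(cohort, config, rng)

    shift = _subtype_shift_matrix(config, regions, cohort["true_subtype"].to_numpy())
    z = shift + _correlated_unit_noise(config, regions, config.n_mdd, rng)
    zmap = pd.DataFrame(
        z, columns=_region_columns(regions), index=cohort["subject_id"]
    )
    return cohort, zmap


def generate_voxel_dataset(
    shape: tuple[int, int, int],
    n_timepoints: int,
    regions: list[RegionSpec],
    seed: int = 0,
    synchrony: float = 0.9,
    noise_sd: float = 1.0,
    parcel_edge: int = 3,
):
    """4D time-series image plus a disjoint block-parcel label atlas.

    Each region occupies one ``parcel_edge``-cubed block; every voxel in a
    parcel shares a latent signal with weight ``sqrt(synchrony)`` plus
    independent noise with weight ``sqrt(1 - synchrony) * noise_sd``.

    Returns ``(data, labels)``: a float (x, y, z, t) array and an int
    (x, y, z) atlas with labels 1..len(regions), 0 background.
    """
    if not 0.0 <= synchrony <= 1.0:
        raise ValueError("synchrony must lie in [0, 1]")
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    nx, ny, nz = (s // parcel_edge for s in shape)
    n_parcels = nx * ny * nz
    if n_parcels < len(regions):
        raise ValueError(
            f"grid {shape} hosts only {n_parcels} parcels of edge {parcel_edge}; "
            f"{len(regions)} required"
        )
    rng = np.random.default_rng(seed)
    data = np.zeros(shape + (n_timepoints,), dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    block = 0
    for r in regions:
        bx, rem = divmod(block, ny * nz)
        by, bz = divmod(rem, nz)
        block += 1
        sl = (
            slice(bx * parcel_edge, (bx + 1) * parcel_edge),
            slice(by * parcel_edge, (by + 1) * parcel_edge),
            slice(bz * parcel_edge, (bz + 1) * parcel_edge),
        )
        latent = rng.standard_normal(n_timepoints)
        nvox = parcel_edge**3
        noise = rng.standard_normal((nvox, n_timepoints)) * noise_sd
        series = np.sqrt(synchrony) * latent + np.sqrt(1.0 - synchrony) * noise
        data[sl] = series.reshape(parcel_edge, parcel_edge, parcel_edge, n_timepoints)
        labels[sl] = r.region_id
    return data, labels


# ---------------------------------------------------------------------------
# TSV round-trips

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"true_subtype": str})


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=True, index_label="subject_id")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def config_to_dict(config: CohortConfig) -> dict:
    return dataclasses.asdict(config)
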