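"""Synthetic landscape generator.

Produces tree inventories, vernacular-name ambiguity tables, canopy point
clouds, soil profile descriptions and site covariates with the statistical
structure the downstream analysis assumes:

* regional species pools with a Fisher log-series rank-abundance profile,
* per-site communities whose expected Fisher's alpha equals the site truth,
* short-lived pioneer (Urticaceae-analogue) stems injected at a controlled
  frequency, acting as the disturbance indicator,
* site-level true diversity generated from the hump-shaped
  diversity-disturbance model
  ``alpha = theta0 + theta1*U + theta2*U**theta3 + theta4*Rain + theta5*Alt + eps``
  with ``U`` the Urticaceae stem frequency in percent, rainfall in mm/yr and
  elevation in m,
* canopy scenes in which true gap fraction increases linearly with pioneer
  frequency, and
* soil profiles (7 described layers) whose within-site dispersion is a
  single ``heterogeneity`` dial.

Everything is deterministic for a fixed seed.
"""
from __future__ import annotations

import dataclasses
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "DEFAULT_THETA",
    "gen_species_pool",
    "gen_site_table",
    "gen_vernacular_mapping",
    "gen_inventory",
    "gen_canopy_scene",
    "gen_soil_samples",
]

# theta1, theta2, theta4, theta5 are the raw-unit coefficients of the
# best 33-site diversity model; theta3 = 2 is the quadratic exponent.
DEFAULT_THETA1 = 10.839859
DEFAULT_THETA2 = -1.480906
DEFAULT_THETA3 = 2.0
DEFAULT_THETA4 = 0.0177333
DEFAULT_THETA5 = 0.0546224

SHORT_LIVED_GENERA = ("Cecropia", "Pourouma")
LONG_LIVED_GENERA = ("Goupia", "Simarouba", "Bagassa", "Ficus")

#: relief classes with (mean, sd) of true Urticaceae stem frequency.
#: Means rise from plains to all-slope relief while the spread narrows.
DEFAULT_RELIEF_CLASSES: dict[str, tuple[float, float]] = {
    "PLN": (0.012, 0.012),
    "MCX": (0.020, 0.012),
    "PLT": (0.025, 0.010),
    "SLO": (0.035, 0.007),
}


def _solve_theta0(
    theta: Sequence[float],
    urti_pct_mid: float,
    rainfall_mid: float,
    elevation_mid: float,
    target_alpha: float = 165.0,
) -> float:
    """Intercept such that the noise-free alpha at mid covariates hits
    ``target_alpha`` (the midpoint of the plausible 134-194 band)."""
    _, t1, t2, t3, t4, t5 = theta
    return target_alpha - (
        t1 * urti_pct_mid
        + t2 * urti_pct_mid**t3
        + t4 * rainfall_mid
        + t5 * elevation_mid
    )


@dataclasses.dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic landscape.

    ``theta`` holds (theta0..theta5) of the diversity model in raw units
    (U in percent, rainfall mm/yr, elevation m).  ``theta[0] = None`` asks
    for an intercept placing noise-free alphas near 165 at mid covariates.
    """

    n_sites: int = 33
    theta: tuple = (None, DEFAULT_THETA1, DEFAULT_THETA2, DEFAULT_THETA3,
                    DEFAULT_THETA4, DEFAULT_THETA5)
    sigma: float = 10.0
    rainfall_range: tuple = (2000.0, 4000.0)
    elevation_range: tuple = (0.0, 830.0)
    relief_classes: Mapping[str, tuple] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RELIEF_CLASSES))
    ambiguity: float = 0.6
    n_stems_per_site: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.theta) != 6:
            raise ValueError("theta must have 6 entries (theta0..theta5)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.ambiguity <= 1.0:
            raise ValueError("ambiguity must lie in [0, 1]")
        for name, (lo, hi) in (("rainfall_range", self.rainfall_range),
                               ("elevation_range", self.elevation_range)):
            if not hi > lo:
                raise ValueError(f"{name} must be a non-degenerate interval")
        for cls, (mean, sd) in self.relief_classes.items():
            if not 0.0 <= mean <= 0.1:
                raise ValueError(
                    f"relief class {cls}: Urticaceae mean {mean} outside [0, 0.1]")
            if sd < 0:
                raise ValueError(f"relief class {cls}: negative sd")
        if self.n_sites < 1 or self.n_stems_per_site < 1:
            raise ValueError("n_sites and n_stems_per_site must be positive")

    def resolved_theta(self) -> np.ndarray:
        theta = list(self.theta)
        if theta[0] is None:
            u_mid = 100.0 * float(np.mean(
                [m for m, _ in self.relief_classes.values()]))
            theta[0] = _solve_theta0(
                [0.0] + theta[1:],
                u_mid,
                float(np.mean(self.rainfall_range)),
                float(np.mean(self.elevation_range)),
            )
        return np.asarray(theta, dtype=float)


def _log_series_profile(n_species: int, alpha_regional: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Relative abundances with a log-series rank-abundance shape.

    The implied community size is the N at which a Fisher sample of
    ``alpha_regional`` holds ``n_species`` species; abundances are then
    i.i.d. logarithmic-distribution draws, sorted and normalized.
    """
    n_ref = alpha_regional * np.expm1(n_species / alpha_regional)
    x = n_ref / (n_ref + alpha_regional)
    k = rng.logseries(x, size=n_species)
    ab = np.sort(k)[::-1].astype(float)
    return ab / ab.sum()


def gen_species_pool(
    n_species: int,
    alpha_regional: float = 180.0,
    seed: int = 0,
    n_short_lived: int | None = None,
    n_long_lived: int | None = None,
) -> pd.DataFrame:
    """Regional species pool with traits and a log-series abundance profile.

    Returns a DataFrame with columns ``species_id, genus, family,
    rel_abundance, wsg, pioneer_class``; abundances sum to one.  Default
    pioneer-guild sizes scale to 18 short-lived + 42 long-lived species at
    the reference pool size of 1,581 (the guild of 60 pioneers).
    """
    if n_species < 10:
        raise ValueError("n_species must be >= 10")
    if alpha_regional <= 0:
        raise ValueError("alpha_regional must be > 0")
    if n_short_lived is None:
        n_short_lived = min(18, max(2, round(0.0114 * n_species)))
    if n_long_lived is None:
        n_long_lived = min(42, max(2, round(0.0266 * n_species)))
    if n_short_lived < 2 or n_long_lived < 1:
        raise ValueError("pioneer guild sizes too small")
    if n_short_lived + n_long_lived > n_species - 2:
        raise ValueError(
            f"n_species={n_species} too small to host {n_short_lived} short-lived "
            f"and {n_long_lived} long-lived pioneer species")

    rng = np.random.default_rng(seed)
    rel_ab = _log_series_profile(n_species, alpha_regional, rng)

    pioneer_class = np.array(["none"] * n_species, dtype=object)
    idx = rng.permutation(n_species)
    short_idx = idx[:n_short_lived]
    long_idx = idx[n_short_lived:n_short_lived + n_long_lived]
    pioneer_class[short_idx] = "short_lived"
    pioneer_class[long_idx] = "long_lived"

    genus = np.empty(n_species, dtype=object)
    family = np.empty(n_species, dtype=object)
    # short-lived pioneers split between the two Urticaceae genera
    half = (n_short_lived + 1) // 2
    for j, i in enumerate(short_idx):
        genus[i] = SHORT_LIVED_GENERA[0] if j < half else SHORT_LIVED_GENERA[1]
        family[i] = "Urticaceae"
    for j, i in enumerate(long_idx):
        genus[i] = LONG_LIVED_GENERA[j % len(LONG_LIVED_GENERA)]
        family[i] = "F_" + genus[i]
    # remaining species grouped into genera of mean size ~7, mirroring the
    # coarseness of a ~230-name vernacular nomenclature over ~1,600 species
    rest = idx[n_short_lived + n_long_lived:]
    g = 0
    pos = 0
    while pos < len(rest):
        size = int(rng.integers(3, 13))
        for i in rest[pos:pos + size]:
            genus[i] = f"G{g:04d}"
            family[i] = f"F{g // 4:03d}"
        pos += size
        g += 1

    wsg = np.where(
        pioneer_class == "short_lived", rng.normal(0.35, 0.05, n_species),
        np.where(pioneer_class == "long_lived", rng.normal(0.45, 0.07, n_species),
                 rng.normal(0.65, 0.12, n_species)))
    wsg = np.clip(wsg, 0.12, 1.35)

    return pd.DataFrame({
        "species_id": [f"sp{i:04d}" for i in range(n_species)],
        "genus": genus,
        "family": family,
        "rel_abundance": rel_ab,
        "wsg": wsg,
        "pioneer_class": pioneer_class,
    })


def gen_site_table(config: GeneratorConfig) -> pd.DataFrame:
    """Site-level ground truth: covariates, true disturbance, true alpha.

    alpha_true follows the power-term diversity model with Gaussian noise of
    sd ``config.sigma``; a draw producing alpha <= 0 is resampled (up to 100
    times, then an error is raised).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    theta = config.resolved_theta()
    t0, t1, t2, t3, t4, t5 = theta
    classes = list(config.relief_classes)
    n = config.n_sites

    relief = np.array([classes[i % len(classes)] for i in range(n)])
    rng.shuffle(relief)
    rain = rng.uniform(*config.rainfall_range, size=n)
    # all-slope relief sits higher in the landscape; bias its elevations up
    lo, hi = config.elevation_range
    elev = rng.uniform(lo, hi, size=n)
    elev = np.where(relief == "SLO", lo + 0.5 * (hi - lo)
                    + 0.5 * (elev - lo), elev)
    coords = rng.uniform(0.0, 300.0, size=(n, 2))

    means = np.array([config.relief_classes[c][0] for c in relief])
    sds = np.array([config.relief_classes[c][1] for c in relief])
    urti = np.clip(rng.normal(means, sds), 0.0, 0.1)

    u_pct = 100.0 * urti
    mu = t0 + t1 * u_pct + t2 * u_pct**t3 + t4 * rain + t5 * elev
    alpha = mu + rng.normal(0.0, config.sigma, size=n)
    for _ in range(100):
        bad = alpha <= 0
        if not bad.any():
            break
        alpha[bad] = mu[bad] + rng.normal(0.0, config.sigma, size=int(bad.sum()))
    else:
        raise RuntimeError("could not generate positive alpha_true for all sites")

    # Bray-2 P as a pedogenesis-age proxy: low everywhere, weakly decreasing
    # with alpha, never above ~4 mg/kg
    p_bray2 = np.clip(4.0 - 0.02 * (alpha - 130.0)
                      + rng.normal(0.0, 0.6, n), 0.2, 4.0)
    clay = np.where(relief == "SLO", rng.uniform(45, 65, n),
                    rng.uniform(15, 45, n))
    silt = rng.uniform(10, 30, n)
    scale = np.maximum(clay + silt, 95.0) / 95.0
    clay, silt = clay / scale, silt / scale
    sand = 100.0 - clay - silt

    understory = np.maximum(5.0 + 0.20 * alpha + rng.normal(0.0, 2.0, n), 1.0)

    return pd.DataFrame({
        "site_id": [f"S{i + 1:02d}" for i in range(n)],
        "relief_class": relief,
        "rainfall_mm": rain,
        "elevation_m": elev,
        "elevation_range_m": np.where(relief == "SLO",
                                      rng.uniform(150, 400, n),
                                      rng.uniform(20, 150, n)),
        "x_km": coords[:, 0],
        "y_km": coords[:, 1],
        "urti_freq_true": urti,
        "alpha_true": alpha,
        "understory_alpha_true": understory,
        "p_bray2": p_bray2,
        "cec": rng.uniform(2.0, 12.0, n),
        "ph": rng.uniform(3.8, 5.5, n),
        "sum_bases": rng.uniform(0.2, 3.0, n),
        "clay_pct": clay,
        "silt_pct": silt,
        "sand_pct": sand,
    })


def gen_vernacular_mapping(pool: pd.DataFrame, ambiguity: float,
                           seed: int = 0) -> pd.DataFrame:
    """Vernacular-name table: each species is covered by exactly one name.

    With probability ``ambiguity`` a species is filed under its genus's
    shared group name (several congeners per name, candidate probabilities
    proportional to pool abundance); otherwise it gets a private name.
    ``ambiguity=0`` yields only singleton names.

    Returns columns ``vernacular, species_id, prob``.
    """
    if not 0.0 <= ambiguity <= 1.0:
        raise ValueError("ambiguity must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    grouped = (rng.uniform(size=len(pool)) < ambiguity)
    rows = []
    for genus, sub in pool.groupby("genus", sort=True):
        members = sub.index[grouped[sub.index]]
        if len(members) >= 2:
            probs = pool.loc[members, "rel_abundance"].to_numpy()
            probs = probs / probs.sum()
            for i, p in zip(members, probs):
                rows.append((f"grp_{genus}", pool.at[i, "species_id"], p))
            singles = sub.index.difference(members)
        else:
            singles = sub.index
        for i in singles:
            rows.append((f"v_{pool.at[i, 'species_id']}",
                         pool.at[i, "species_id"], 1.0))
    return pd.DataFrame(rows, columns=["vernacular", "species_id", "prob"])


def _site_community(alpha: float, n_stems: int, pool_species: np.ndarray,
                    pool_weights: np.ndarray, rng: np.random.Generator,
                    community_mult: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Realize a site community as a Fisher log-series sample.

    Species abundances at each count k are independent Poisson with mean
    ``alpha * x**k / k`` (x set by a community size = community_mult *
    n_stems); the inventory then subsamples that community multinomially,
    which preserves Fisher's alpha.
    """
    # cap the community size so its expected richness alpha*ln(1+N/alpha)
    # stays comfortably inside the pool
    cap = alpha * np.expm1(0.9 * len(pool_species) / alpha)
    n_comm = min(community_mult * n_stems, cap)
    if n_comm < 5 * n_stems:
        raise ValueError(
            f"pool of {len(pool_species)} species too small to host a "
            f"community of alpha {alpha:.0f} at {n_stems} stems")
    for _ in range(5):
        x = n_comm / (n_comm + alpha)
        kmax = int(np.ceil(np.log(1e-12 / alpha) / np.log(x)))
        k = np.arange(1, kmax + 1)
        counts = np.repeat(k, rng.poisson(alpha * x**k / k))
        s_comm = len(counts)
        if s_comm <= len(pool_species):
            break
        n_comm *= 0.8  # unlucky richness draw: shrink and redraw
    else:
        raise ValueError(
            f"site community needs {s_comm} species but the pool offers only "
            f"{len(pool_species)}; enlarge the pool or lower alpha")
    chosen = rng.choice(len(pool_species), size=s_comm, replace=False,
                        p=pool_weights / pool_weights.sum())
    # most abundant community slot -> most abundant chosen pool species
    order = np.argsort(pool_weights[chosen])[::-1]
    species = pool_species[chosen[order]]
    rel = np.sort(counts)[::-1].astype(float)
    return species, rel / rel.sum()


def gen_inventory(
    site: Mapping,
    pool: pd.DataFrame,
    n_stems: int,
    ambiguity: float,
    seed: int = 0,
    mapping: pd.DataFrame | None = None,
    community_mult: int = 50,
    transect_length_m: float = 3000.0,
    n_transects: int = 3,
    long_lived_base: float = 0.01,
    long_lived_slope: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stem inventory of one site plus the vernacular mapping used.

    Stems (DBH > 17.5 cm) are multinomial draws from a realized log-series
    community whose parameter is ``site['alpha_true']``; short-lived pioneer
    stems are then injected at rate ``site['urti_freq_true']``.  Long-lived
    pioneers ride the same disturbance gradient at rate
    ``long_lived_base + long_lived_slope * urti_freq_true`` (the whole
    pioneer guild responds to canopy openness, so the community
    wood-density signal survives removal of the short-lived genera).  The
    returned stem table carries the true ``species_id`` alongside the
    observed vernacular name; writers drop the truth column.
    """
    if n_stems < 1:
        raise ValueError("n_stems must be >= 1")
    u = float(site["urti_freq_true"])
    if u > 1.0:
        raise ValueError("urti_freq_true must not exceed 1")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed), 3, zlib.crc32(str(site["site_id"]).encode())]))

    if mapping is None:
        mapping = gen_vernacular_mapping(pool, ambiguity, seed=seed)

    pioneer = pool["pioneer_class"].to_numpy()
    bg = pool[pioneer == "none"]
    species, rel = _site_community(
        float(site["alpha_true"]), n_stems,
        bg["species_id"].to_numpy(), bg["rel_abundance"].to_numpy(),
        rng, community_mult)
    draws = rng.choice(len(species), size=n_stems, p=rel)
    stem_species = draws_species = species[draws]

    # inject the pioneer guild along the disturbance gradient: short-lived
    # at frequency u, long-lived at base + slope * u
    u_long = max(0.0, long_lived_base + long_lived_slope * u)
    if u + u_long > 1.0:
        raise ValueError("pioneer injection rates exceed 1; lower the link")
    roll = rng.uniform(size=n_stems)
    stem_species = draws_species.copy()
    for lo, hi, cls in ((0.0, u, "short_lived"),
                        (u, u + u_long, "long_lived")):
        pick = (roll >= lo) & (roll < hi)
        if pick.any():
            guild = pool[pioneer == cls]
            w = guild["rel_abundance"].to_numpy()
            stem_species[pick] = rng.choice(
                guild["species_id"].to_numpy(), size=int(pick.sum()),
                p=w / w.sum())

    name_of = dict(zip(mapping["species_id"], mapping["vernacular"]))
    vern = np.array([name_of[s] for s in stem_species], dtype=object)

    stems = pd.DataFrame({
        "site_id": site["site_id"],
        "transect_id": rng.integers(1, n_transects + 1, size=n_stems),
        "pos_m": rng.uniform(0.0, transect_length_m, size=n_stems),
        "vernacular": vern,
        "dbh_cm": 17.6 + rng.exponential(12.0, size=n_stems),
        "species_id_true": stem_species,
    })
    return stems, mapping


def gen_canopy_scene(
    extent_m: tuple,
    urti_freq: float,
    link: tuple = (0.005, 2.0),
    seed: int = 0,
    ground_density: float = 0.3,
    first_density: float = 0.6,
    canopy_height: float = 30.0,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Synthetic LiDAR-like scene: ground + first-return points and a transect.

    True gap area fraction is ``a + b * urti_freq`` with ``(a, b) = link``;
    gaps are unioned random disks rasterized on a 1-m grid.  Returns
    ``(points, transect, info)`` where ``points`` has columns ``x y z cls``
    (cls in {"first", "ground"}), ``transect`` is an (n, 2) polyline, and
    ``info`` records the realized gap fraction.
    """
    xmin, ymin, xmax, ymax = (float(v) for v in extent_m)
    w, h = xmax - xmin, ymax - ymin
    if w < 200 or h < 200:
        raise ValueError("extent must be at least 200 x 200 m")
    a, b = link
    target = a + b * urti_freq
    if not 0.0 <= target < 1.0:
        raise ValueError(f"gap-fraction link yields {target}, outside [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))

    nx, ny = int(round(w)), int(round(h))
    gap = np.zeros((ny, nx), dtype=bool)
    if target > 0:
        gx, gy = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5)
        for _ in range(100000):
            if gap.mean() >= target:
                break
            cx, cy = rng.uniform(0, nx), rng.uniform(0, ny)
            r = rng.uniform(8.0, 25.0)
            gap |= (gx - cx) ** 2 + (gy - cy) ** 2 <= r * r

    def terrain(x, y):
        return (20.0 * np.sin((x - xmin) / 300.0)
                + 15.0 * np.cos((y - ymin) / 250.0)
                + 0.01 * (x - xmin))

    n_ground = rng.poisson(ground_density * w * h)
    xg = rng.uniform(xmin, xmax, n_ground)
    yg = rng.uniform(ymin, ymax, n_ground)
    zg = terrain(xg, yg) + rng.normal(0.0, 0.05, n_ground)

    n_first = rng.poisson(first_density * w * h)
    xf = rng.uniform(xmin, xmax, n_first)
    yf = rng.uniform(ymin, ymax, n_first)
    ix = np.clip(((xf - xmin)).astype(int), 0, nx - 1)
    iy = np.clip(((yf - ymin)).astype(int), 0, ny - 1)
    in_gap = gap[iy, ix]
    zf = terrain(xf, yf) + np.where(
        in_gap, np.abs(rng.normal(1.0, 0.4, n_first)),
        canopy_height + rng.normal(0.0, 2.0, n_first))

    points = pd.DataFrame({
        "x": np.concatenate([xf, xg]),
        "y": np.concatenate([yf, yg]),
        "z": np.concatenate([zf, zg]),
        "cls": np.array(["first"] * n_first + ["ground"] * n_ground,
                        dtype=object),
    })
    ymid = 0.5 * (ymin + ymax)
    transect = np.array([[xmin, ymid], [0.5 * (xmin + xmax), ymid],
                         [xmax, ymid]])
    info = {"gap_fraction_true": float(gap.mean()),
            "gap_fraction_target": float(target)}
    return points, transect, info


# ordered descriptor levels for the 7 described soil layers
SOIL_ORDINALS = {"moisture": 5, "texture": 6, "roots": 5,
                 "coarse_frag": 5, "redox": 4}
SOIL_COLOURS = ("red", "yellow", "brown", "grey", "white", "black")
N_SOIL_LAYERS = 7


def gen_soil_samples(site: Mapping, n_samples: int, heterogeneity: float,
                     seed: int = 0) -> pd.DataFrame:
    """Field soil descriptions: 7 layers per auger sample around a site
    archetype.  ``heterogeneity`` scales within-site dispersion (0 makes all
    samples identical copies of the archetype)."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed), 5, zlib.crc32(str(site["site_id"]).encode())]))

    # archetype depends deterministically on the site's texture/relief
    clayey = float(site.get("clay_pct", 30.0)) > 45.0
    arch = {}
    for layer in range(1, N_SOIL_LAYERS + 1):
        arch[layer] = {
            "moisture": min(5, 1 + layer // 2),
            "colour": SOIL_COLOURS[0 if clayey else 1]
            if layer > 2 else SOIL_COLOURS[2],
            "texture": min(6, (4 if clayey else 2) + layer // 3),
            "roots": max(0, 4 - layer),
            "coarse_frag": min(4, layer // 2 if clayey else 0),
            "redox": 0 if clayey else min(3, max(0, layer - 4)),
        }

    rows = []
    for s in range(n_samples):
        for layer in range(1, N_SOIL_LAYERS + 1):
            rec = {"sample_id": f"{site['site_id']}_a{s + 1:02d}",
                   "site_id": site["site_id"], "layer": layer}
            for var, n_levels in SOIL_ORDINALS.items():
                lo = 0 if var in ("roots", "coarse_frag", "redox") else 1
                hi = lo + n_levels - 1
                step = int(np.rint(rng.normal(0.0, 2.0 * heterogeneity)))
                rec[var] = int(np.clip(arch[layer][var] + step, lo, hi))
            if rng.uniform() < min(1.0, heterogeneity):
                rec["colour"] = SOIL_COLOURS[rng.integers(len(SOIL_COLOURS))]
            else:
                rec["colour"] = arch[layer]["colour"]
            rows.append(rec)
    cols = ["sample_id", "site_id", "layer", "moisture", "colour", "texture",
            "roots", "coarse_frag", "redox"]
    return pd.DataFrame(rows)[cols]
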