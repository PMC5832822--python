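"""Community diversity and disturbance indicators from stem inventories.

Tree stems are recorded under vernacular (forester) names, each of which may
correspond to one or several botanical species.  Species composition is
therefore simulated: each Monte-Carlo draw assigns every stem one species
from its name's candidate list, Fisher's alpha is computed per draw, and the
spread of the draws quantifies the identification uncertainty.

Fisher's alpha is the diversity parameter of the log-series
species-abundance model, implicitly defined by ``S = alpha * ln(1 + N/alpha)``
for ``S`` species among ``N`` stems; it is insensitive to sample size, which
is what makes it usable across sites with unequal inventory effort.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "fisher_alpha",
    "assign_species",
    "composition_draws",
    "estimate_diversity",
    "compute_indicators",
    "DiversityEstimate",
    "IndicatorSet",
]

logger = logging.getLogger(__name__)


def fisher_alpha(s: int, n: int) -> float:
    """Solve ``s = alpha * ln(1 + n/alpha)`` for alpha.

    Parameters
    ----------
    s : species count, with ``1 <= s < n``
    n : stem count

    The left side is strictly increasing in alpha, so a bracketed Brent
    search on ``[1e-6, 1e7]`` converges to the unique root.

    Raises
    ------
    ValueError
        if ``s >= n`` (every stem a singleton: alpha diverges) or either
        count is non-positive.
    """
    if s <= 0 or n <= 0:
        raise ValueError(f"counts must be positive, got s={s}, n={n}")
    if s >= n:
        raise ValueError(
            f"s={s} >= n={n}: Fisher's alpha diverges when all stems are singletons")
    f = lambda a: a * np.log1p(n / a) - s
    # near s = n the root grows like n^2 / (2 (n - s)); widen the bracket
    hi = max(1e7, 2.0 * n * n / (n - s))
    return float(optimize.brentq(f, 1e-6, hi, rtol=8.9e-16, xtol=1e-12))


def _check_mapping(records: pd.DataFrame, mapping: pd.DataFrame) -> None:
    names_seen = set(records["vernacular"])
    names_known = set(mapping["vernacular"])
    missing = names_seen - names_known
    if missing:
        raise ValueError(
            "unmapped vernacular name(s): " + ", ".join(sorted(missing)[:10]))
    sums = mapping.groupby("vernacular")["prob"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-9]
    if len(bad):
        raise ValueError(
            "candidate probabilities do not sum to 1 for name(s): "
            + ", ".join(str(v) for v in bad.index[:10]))


def assign_species(records: pd.DataFrame, mapping: pd.DataFrame,
                   rng: np.random.Generator) -> np.ndarray:
    """One Monte-Carlo composition draw.

    Every stem is assigned a species drawn independently from its vernacular
    name's candidate distribution.  Returns an array of species ids aligned
    with ``records``.
    """
    _check_mapping(records, mapping)
    out = np.empty(len(records), dtype=object)
    vern = records["vernacular"].to_numpy()
    for name, cand in mapping.groupby("vernacular"):
        idx = np.flatnonzero(vern == name)
        if len(idx) == 0:
            continue
        species = cand["species_id"].to_numpy()
        if len(species) == 1:
            out[idx] = species[0]
        else:
            p = cand["prob"].to_numpy()
            out[idx] = rng.choice(species, size=len(idx), p=p / p.sum())
    return out


@dataclasses.dataclass
class DiversityEstimate:
    """Per-site Fisher's-alpha distribution over composition draws."""

    site_id: str
    alpha_draws: np.ndarray
    species_counts: np.ndarray
    n_stems: int
    n_rejected: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.alpha_draws))

    @property
    def sd(self) -> float:
        # identical draws (unambiguous mapping) must give exactly zero,
        # not float-rounding dust from the mean subtraction
        if len(self.alpha_draws) < 2 or np.ptp(self.alpha_draws) == 0.0:
            return 0.0
        return float(np.std(self.alpha_draws, ddof=1))

    @property
    def q025(self) -> float:
        return float(np.quantile(self.alpha_draws, 0.025))

    @property
    def q975(self) -> float:
        return float(np.quantile(self.alpha_draws, 0.975))

    def summary(self) -> dict:
        return {"site_id": self.site_id, "alpha_mean": self.mean,
                "alpha_sd": self.sd, "q025": self.q025, "q975": self.q975,
                "n_stems": self.n_stems}


def _species_draw_matrix(records: pd.DataFrame, mapping: pd.DataFrame,
                         n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """(n_draws, n_stems) matrix of integer species codes.

    Stems under singleton names are constant across draws; only ambiguous
    names are redrawn, which keeps the Monte-Carlo loop vectorized.
    """
    codes = {s: i for i, s in enumerate(pd.unique(mapping["species_id"]))}
    vern = records["vernacular"].to_numpy()
    n = len(records)
    mat = np.empty((n_draws, n), dtype=np.int32)
    for name, cand in mapping.groupby("vernacular"):
        idx = np.flatnonzero(vern == name)
        if len(idx) == 0:
            continue
        sp_codes = np.array([codes[s] for s in cand["species_id"]],
                            dtype=np.int32)
        if len(sp_codes) == 1:
            mat[:, idx] = sp_codes[0]
        else:
            p = cand["prob"].to_numpy()
            draws = rng.choice(sp_codes, size=(n_draws, len(idx)),
                               p=p / p.sum())
            mat[:, idx] = draws
    return mat


def _richness_per_row(mat: np.ndarray) -> np.ndarray:
    """Distinct-value count per row of an integer matrix."""
    srt = np.sort(mat, axis=1)
    return 1 + (np.diff(srt, axis=1) != 0).sum(axis=1)


def composition_draws(records: pd.DataFrame, mapping: pd.DataFrame,
                      n_draws: int, seed: int = 0) -> np.ndarray:
    """(n_draws, n_stems) matrix of species ids: repeated composition
    draws, ready for :func:`compute_indicators`."""
    _check_mapping(records, mapping)
    rng = np.random.default_rng(seed)
    mat = _species_draw_matrix(records, mapping, n_draws, rng)
    species = pd.unique(mapping["species_id"])
    return np.asarray(species, dtype=object)[mat]


def estimate_diversity(records: pd.DataFrame, mapping: pd.DataFrame,
                       n_draws: int = 1000, seed: int = 0,
                       site_id: str | None = None) -> DiversityEstimate:
    """Fisher's alpha with vernacular-name uncertainty propagated by
    Monte Carlo.

    One alpha per composition draw; draws in which every stem is a singleton
    species (``s == n``, alpha divergent) are rejected and logged.  With an
    unambiguous mapping all draws coincide and the sd is exactly zero.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if n_draws < 100:
        logger.warning("n_draws=%d is low; uncertainty summaries will be noisy",
                       n_draws)
    _check_mapping(records, mapping)
    if site_id is None:
        site_id = str(records["site_id"].iloc[0]) if "site_id" in records else ""
    rng = np.random.default_rng(seed)
    mat = _species_draw_matrix(records, mapping, n_draws, rng)
    s = _richness_per_row(mat)
    n = mat.shape[1]
    ok = s < n
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%d/%d draws rejected (all stems singletons)",
                       n_rejected, n_draws)
    if not ok.any():
        raise ValueError("every composition draw had s == n; alpha undefined")
    uniq, inv = np.unique(s[ok], return_inverse=True)
    alpha_of = np.array([fisher_alpha(int(si), n) for si in uniq])
    return DiversityEstimate(site_id=site_id, alpha_draws=alpha_of[inv],
                             species_counts=s[ok], n_stems=n,
                             n_rejected=n_rejected)


@dataclasses.dataclass
class IndicatorSet:
    """Disturbance indicators per site, each as a distribution over draws."""

    site_id: str
    urti_freq: np.ndarray       # short-lived-pioneer stem frequency, per draw
    pioneer_freq: np.ndarray    # all-pioneer stem frequency, per draw
    wsg_mean: np.ndarray        # community mean wood specific gravity, g/cm3
    wsg_mean_excl: np.ndarray   # same, excluding the excluded taxon set
    n_imputed_wsg: int = 0

    def summary(self) -> dict:
        return {
            "site_id": self.site_id,
            "urti_freq": float(np.mean(self.urti_freq)),
            "pioneer_freq": float(np.mean(self.pioneer_freq)),
            "wsg_mean": float(np.mean(self.wsg_mean)),
            "wsg_mean_excl": float(np.mean(self.wsg_mean_excl)),
        }


def impute_wsg(traits: pd.DataFrame) -> tuple[pd.Series, int]:
    """Fill missing wood specific gravity: genus mean, then family mean,
    then the global mean.  Returns the filled series and the imputation
    count."""
    wsg = traits["wsg"].copy()
    missing = wsg.isna()
    n_missing = int(missing.sum())
    if n_missing:
        genus_mean = traits.groupby("genus")["wsg"].transform("mean")
        wsg = wsg.fillna(genus_mean)
        family_mean = traits.groupby("family")["wsg"].transform("mean")
        wsg = wsg.fillna(family_mean)
        wsg = wsg.fillna(traits["wsg"].mean())
    return wsg, n_missing


def compute_indicators(
    draws: np.ndarray,
    traits: pd.DataFrame,
    pioneer_species: Iterable[str] | None = None,
    short_lived_species: Iterable[str] | None = None,
    exclude_for_wsg: Iterable[str] | None = None,
    site_id: str = "",
) -> IndicatorSet:
    """Disturbance indicators from composition draws.

    Parameters
    ----------
    draws : (n_draws, n_stems) array of species ids (or a 1-D single draw)
    traits : table with ``species_id, genus, family, wsg, pioneer_class``
    pioneer_species : the full pioneer guild; defaults to all species whose
        ``pioneer_class`` is not "none"
    short_lived_species : the short-lived subset (the Urticaceae-analogue
        indicator); defaults to ``pioneer_class == "short_lived"``
    exclude_for_wsg : species dropped from both numerator and denominator of
        the robustness-check community WSG mean; defaults to the short-lived
        set

    The urti frequency is the share of stems in short-lived-pioneer species;
    the WSG mean is stem-weighted (stems are the inventory's natural unit).
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=object))
    if draws.shape[1] == 0:
        raise ValueError("empty stem set")
    traits = traits.reset_index(drop=True)
    wsg_filled, n_imputed = impute_wsg(traits)
    if short_lived_species is None:
        short_lived_species = set(
            traits.loc[traits["pioneer_class"] == "short_lived", "species_id"])
    else:
        short_lived_species = set(short_lived_species)
    if pioneer_species is None:
        pioneer_species = set(
            traits.loc[traits["pioneer_class"] != "none", "species_id"])
    else:
        pioneer_species = set(pioneer_species)
    if exclude_for_wsg is None:
        exclude_for_wsg = short_lived_species
    else:
        exclude_for_wsg = set(exclude_for_wsg)

    known = set(traits["species_id"])
    present = set(np.unique(draws))
    unknown = present - known
    if unknown:
        raise ValueError("species without trait rows: "
                         + ", ".join(sorted(map(str, unknown))[:10]))

    code = {s: i for i, s in enumerate(traits["species_id"])}
    codemat = np.vectorize(code.__getitem__, otypes=[np.int32])(draws)
    wsg_arr = wsg_filled.to_numpy()
    is_short = np.array([s in short_lived_species for s in traits["species_id"]])
    is_pion = np.array([s in pioneer_species for s in traits["species_id"]])
    is_excl = np.array([s in exclude_for_wsg for s in traits["species_id"]])

    short_mask = is_short[codemat]
    pion_mask = is_pion[codemat]
    excl_mask = is_excl[codemat]
    stem_wsg = wsg_arr[codemat]

    n_stems = draws.shape[1]
    urti = short_mask.mean(axis=1)
    pioneer = pion_mask.mean(axis=1)
    wsg_mean = stem_wsg.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kept = ~excl_mask
        wsg_excl = np.where(kept.any(axis=1),
                            np.nansum(np.where(kept, stem_wsg, np.nan), axis=1)
                            / kept.sum(axis=1), np.nan)

    return IndicatorSet(site_id=site_id, urti_freq=urti, pioneer_freq=pioneer,
                        wsg_mean=wsg_mean, wsg_mean_excl=wsg_excl,
                        n_imputed_wsg=n_imputed)
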