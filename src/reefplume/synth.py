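"""Synthetic OTU tables and environmental covariates.

The generator emulates the riverine-to-marine community gradient of an
inshore coral-lagoon monitoring transect.  Each sample's expected
composition is a mixture of two endmember communities:

* a riverine endmember (~65 OTUs) dominated by Burkholderiales,
  Sphingobacteriales and Xanthomonadales, and
* a marine endmember (~95 OTUs) dominated by Rickettsiales
  (Pelagibacteraceae), Synechococcales (Prochlorococcus/Synechococcus),
  Thermoplasmata E2 (Marine Group II) and Acidimicrobiales (OCS155),
  with a dry/wet seasonal shift between Pelagibacteraceae and Marine
  Group II.

The riverine weight w of a sample follows a logistic link on its
cumulative river-exposure index (conc.d) plus a seasonal offset, so w is
monotone in exposure within a season and stays in [0, 1].  Read counts
are drawn multinomially after multiplying expected cell abundances by
16S gene copy numbers and renormalising, deliberately injecting the
copy-number bias that downstream correction removes.  Eukaryote reads
are appended at a configurable contamination rate.

Environmental covariates follow a four-factor model: four independent
standard-normal factor scores per sample, a loading matrix with primary
loadings of 0.8 (rainfall + river discharge; particulates + chlorophyll
+ diuron; DIN + salinity, salinity loading negatively; temperature +
solar exposure) and unique noise of sd 0.6.  The latent factor scores
are stored so factor-recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .diversity import OtuTable
from .exposure import SiteRecord, classify_site
from .transport import ConfigError

__all__ = [
    "EndmemberCommunity",
    "ScenarioConfig",
    "EnvTable",
    "riverine_endmember",
    "marine_endmember",
    "generate_environment",
    "generate_otu_table",
    "estimate_riverine_fraction",
    "water_quality_index",
    "rolling_7day_mean",
]


@dataclass
class EndmemberCommunity:
    """A reference community: OTU ids, taxonomy, copy numbers, abundances."""

    label: str  # 'riverine' | 'marine'
    taxa: pd.DataFrame  # index: OTU id; columns: taxonomy, copy_number, abundance

    def __post_init__(self) -> None:
        ab = self.taxa["abundance"]
        if not np.isclose(ab.sum(), 1.0, atol=1e-9):
            raise ConfigError(f"{self.label} endmember abundances sum to {ab.sum():.6f}, not 1")
        if (self.taxa["copy_number"] <= 0).any():
            raise ConfigError("copy numbers must be positive")


def _taxa_block(prefix, order_specs, copy_numbers):
    """Build a block of OTUs from (order-path, n_otus, total_abundance) specs.

    Within each order, OTU abundances decay geometrically (ratio 0.8), a
    crude rank-abundance shape typical of amplicon profiles.
    """
    rows = []
    for (path, n_otus, total) in order_specs:
        weights = 0.8 ** np.arange(n_otus)
        weights = weights / weights.sum() * total
        order = path.split(";")[3].strip().lstrip("o__")
        for k in range(n_otus):
            rows.append(
                {
                    "otu_id": f"{prefix}_{order}_{k:03d}",
                    "taxonomy": path,
                    "copy_number": copy_numbers[path],
                    "abundance": weights[k],
                }
            )
    df = pd.DataFrame(rows).set_index("otu_id")
    return df


def riverine_endmember() -> EndmemberCommunity:
    """Default riverine endmember: 65 OTUs, no marine clades.

    Copy numbers are lineage-typical small integers (soil/freshwater
    Betaproteobacteria and Bacteroidetes carry more 16S operons than
    streamlined marine picoplankton).
    """
    specs = [
        ("k__Bacteria; p__Proteobacteria; c__Betaproteobacteria; o__Burkholderiales; f__Comamonadaceae; g__Limnohabitans; s__", 20, 0.35),
        ("k__Bacteria; p__Bacteroidetes; c__Sphingobacteriia; o__Sphingobacteriales; f__Chitinophagaceae; g__; s__", 15, 0.25),
        ("k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Xanthomonadales; f__Xanthomonadaceae; g__; s__", 10, 0.15),
        ("k__Bacteria; p__Bacteroidetes; c__Flavobacteriia; o__Flavobacteriales; f__Flavobacteriaceae; g__; s__", 10, 0.15),
        ("k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales; f__; g__; s__", 10, 0.10),
    ]
    copies = {specs[0][0]: 5.0, specs[1][0]: 4.0, specs[2][0]: 4.0, specs[3][0]: 3.0, specs[4][0]: 3.0}
    return EndmemberCommunity(label="riverine", taxa=_taxa_block("riv", specs, copies))


def marine_endmember() -> EndmemberCommunity:
    """Default marine endmember: 95 OTUs.

    Order-level means are calibrated to the lagoon baseline this package
    models: Rickettsiales at 29.6% of the marine community and
    Thermoplasmata E2 (Marine Group II) at 17.7%.
    """
    specs = [
        ("k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rickettsiales; f__Pelagibacteraceae; g__Pelagibacter; s__", 25, 0.296),
        ("k__Archaea; p__Euryarchaeota; c__Thermoplasmata; o__E2; f__Marine group II; g__; s__", 15, 0.177),
        ("k__Bacteria; p__Cyanobacteria; c__Synechococcophycideae; o__Synechococcales; f__Synechococcaceae; g__Prochlorococcus; s__", 15, 0.20),
        ("k__Bacteria; p__Actinobacteria; c__Acidimicrobiia; o__Acidimicrobiales; f__OCS155; g__; s__", 10, 0.08),
        ("k__Bacteria; p__Bacteroidetes; c__Flavobacteriia; o__Flavobacteriales; f__Flavobacteriaceae; g__; s__", 15, 0.12),
        ("k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Oceanospirillales; f__Halomonadaceae; g__; s__", 15, 0.127),
    ]
    copies = {specs[0][0]: 1.0, specs[1][0]: 1.0, specs[2][0]: 2.0, specs[3][0]: 2.0, specs[4][0]: 3.0, specs[5][0]: 4.0}
    return EndmemberCommunity(label="marine", taxa=_taxa_block("mar", specs, copies))


def _euk_taxa() -> pd.DataFrame:
    rows = []
    for k, (name, genus) in enumerate(
        [("Anthoathecata", "Merona"), ("Calanoida", ""), ("Pennales", ""), ("Peridiniales", ""), ("Mamiellales", "")]
    ):
        rows.append(
            {
                "otu_id": f"euk_{name}_{k:03d}",
                "taxonomy": f"k__Eukaryota; p__; c__; o__{name}; f__; g__{genus}; s__",
                "copy_number": 1.0,
                "abundance": 1.0 / 5,
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")


# default logistic-mixing calibration: w(0) ~= 0.05 at an unexposed marine
# site and w(20 conc.d) = 0.8
MIX_INTERCEPT = -3.0
MIX_SLOPE = float((logit(0.8) - MIX_INTERCEPT) / 20.0)


@dataclass
class ScenarioConfig:
    """Study design for the synthetic generator.

    sites : monitoring sites with categories.
    dates : sampling dates, each labelled wet/dry by ``season_of``.
    depth_range : per-sample sequencing depth drawn uniformly (inclusive).
    mix_slope, mix_intercept : logistic link from exposure (conc.d) to the
        riverine weight w.
    season_offset_wet : additive wet-season shift on the logit of w.
    marine_season_shift : fractional dry-season boost of Pelagibacteraceae
        (matched by a wet-season boost of Marine Group II).
    euk_rate : expected eukaryote reads as a fraction of sample depth.
    seed : generator seed; identical seeds give identical tables.
    """

    sites: list[SiteRecord]
    dates: list[date]
    depth_range: tuple[int, int] = (800, 1200)
    mix_slope: float = MIX_SLOPE
    mix_intercept: float = MIX_INTERCEPT
    season_offset_wet: float = 0.7
    marine_season_shift: float = 0.35
    euk_rate: float = 0.05
    wet_months: tuple[int, ...] = (11, 12, 1, 2, 3)
    seed: int = 0

    def season_of(self, when: date) -> str:
        return "wet" if when.month in self.wet_months else "dry"

    def samples(self) -> pd.DataFrame:
        rows = []
        for site in self.sites:
            cat = site.category or classify_site(site)
            for d in self.dates:
                rows.append(
                    {
                        "sample_id": f"{site.id}_{d.isoformat()}",
                        "site_id": site.id,
                        "date": pd.Timestamp(d),
                        "season": self.season_of(d),
                        "category": cat,
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class EnvTable:
    """Per-sample environmental covariates plus the latent factor truth."""

    data: pd.DataFrame  # samples x 14 covariates
    factors: pd.DataFrame  # samples x MR1..MR4 latent scores
    loadings: pd.DataFrame  # truth loading matrix (variables x MR1..MR4)


# the four-factor truth: variable -> (factor, loading)
FACTOR_STRUCTURE = {
    "rain_7d": ("MR1", 0.8),
    "tully_discharge": ("MR1", 0.8),
    "CHLA": ("MR2", 0.8),
    "SS": ("MR2", 0.8),
    "POC": ("MR2", 0.8),
    "PN": ("MR2", 0.8),
    "PP": ("MR2", 0.8),
    "diuron": ("MR2", 0.8),
    "DIN": ("MR3", 0.8),
    "salinity": ("MR3", -0.8),
    "Si": ("MR3", 0.8),
    "water_temp": ("MR4", 0.8),
    "solar_exp_7d": ("MR4", 0.8),
}
NOISE_SD = 0.6


def generate_environment(scenario: ScenarioConfig) -> EnvTable:
    """Draw the 14-variable environmental table from the 4-factor model.

    Observed variables = loadings x independent standard-normal factor
    scores + unique N(0, 0.6) noise, on a standardized (z-score-like)
    scale.  ``bottom_depth`` is site-fixed (shallow near the river, deeper
    offshore) and not factor-driven.
    """
    samples = scenario.samples()
    n = len(samples)
    if n < 2:
        raise ConfigError("need at least 2 samples")
    rng = np.random.default_rng(scenario.seed)

    factor_names = ["MR1", "MR2", "MR3", "MR4"]
    F = rng.standard_normal((n, 4))
    variables = list(FACTOR_STRUCTURE)
    L = np.zeros((len(variables), 4))
    for i, v in enumerate(variables):
        fac, load = FACTOR_STRUCTURE[v]
        L[i, factor_names.index(fac)] = load
    X = F @ L.T + NOISE_SD * rng.standard_normal((n, len(variables)))
    data = pd.DataFrame(X, index=samples.index, columns=variables)

    # site-fixed bathymetry: riverine sites are shallow, marine deeper
    depth_by_cat = {"riverine": 2.0, "plume": 12.0, "marine": 30.0}
    site_depth = {}
    for site_id, sub in samples.groupby("site_id"):
        cat = sub["category"].iloc[0]
        stable = sum(ord(ch) for ch in site_id)  # process-independent site jitter
        site_depth[site_id] = depth_by_cat[cat] + 3.0 * (stable % 7) / 7.0
    data["bottom_depth"] = samples["site_id"].map(site_depth)

    return EnvTable(
        data=data,
        factors=pd.DataFrame(F, index=samples.index, columns=factor_names),
        loadings=pd.DataFrame(L, index=variables, columns=factor_names),
    )


def _season_modulated(marine: EndmemberCommunity, season: str, shift: float) -> pd.Series:
    """Marine endmember with the dry/wet Pelagibacteraceae <-> MGII swing."""
    ab = marine.taxa["abundance"].copy()
    pelagi = marine.taxa["taxonomy"].str.contains("Pelagibacteraceae")
    mgii = marine.taxa["taxonomy"].str.contains("Marine group II")
    if season == "dry":
        ab[pelagi] *= 1.0 + shift
        ab[mgii] *= 1.0 - shift
    else:
        ab[pelagi] *= 1.0 - shift
        ab[mgii] *= 1.0 + shift
    return ab / ab.sum()


def generate_otu_table(
    scenario: ScenarioConfig,
    exposure: pd.Series,
    riverine: EndmemberCommunity | None = None,
    marine: EndmemberCommunity | None = None,
) -> tuple[OtuTable, pd.DataFrame]:
    """Generate a multinomial OTU table along the exposure gradient.

    ``exposure`` maps sample_id -> cumulative exposure (conc.d) at that
    site and date.  Returns the table and a truth frame holding, per
    sample, the riverine weight w, expected depth and design labels.
    The raw counts include the 16S copy-number bias and any eukaryote
    contamination; downstream correction is expected to remove the former.
    """
    riverine = riverine or riverine_endmember()
    marine = marine or marine_endmember()
    samples = scenario.samples()
    missing = samples.index.difference(exposure.index)
    if len(missing):
        raise ConfigError(f"exposure missing for samples: {list(missing)[:5]}")
    rng = np.random.default_rng(scenario.seed + 1)

    universe = pd.concat([riverine.taxa, marine.taxa])
    if universe.index.has_duplicates:
        raise ConfigError("riverine and marine endmembers share OTU ids")
    euk = _euk_taxa()
    all_tax = pd.concat([universe, euk])

    riv_ab = riverine.taxa["abundance"].reindex(universe.index).fillna(0.0).to_numpy()
    copy = universe["copy_number"].to_numpy()

    counts = np.zeros((len(samples), len(all_tax)), dtype=np.int64)
    truth_rows = []
    n_prok = len(universe)
    for s, (sample_id, row) in enumerate(samples.iterrows()):
        x = float(exposure.loc[sample_id])
        offset = scenario.season_offset_wet if row["season"] == "wet" else 0.0
        if row["category"] == "riverine":
            w = 1.0  # the upstream freshwater site carries the pure river community
        else:
            w = float(np.clip(expit(scenario.mix_intercept + scenario.mix_slope * x + offset), 0.0, 1.0))
        mar_ab = (
            _season_modulated(marine, row["season"], scenario.marine_season_shift)
            .reindex(universe.index)
            .fillna(0.0)
            .to_numpy()
        )
        expected = w * riv_ab + (1.0 - w) * mar_ab
        biased = expected * copy
        biased = biased / biased.sum()
        depth = int(rng.integers(scenario.depth_range[0], scenario.depth_range[1] + 1))
        counts[s, :n_prok] = rng.multinomial(depth, biased)
        if scenario.euk_rate > 0:
            n_euk = rng.poisson(scenario.euk_rate * depth)
            if n_euk > 0:
                counts[s, n_prok:] = rng.multinomial(n_euk, euk["abundance"].to_numpy())
        truth_rows.append({"sample_id": sample_id, "w_riverine": w, "depth": depth, "exposure": x})

    table = OtuTable(
        counts=pd.DataFrame(counts, index=samples.index, columns=all_tax.index),
        taxonomy=all_tax["taxonomy"],
        copy_number=all_tax["copy_number"],
        domain=pd.Series(
            ["prokaryote"] * n_prok + ["eukaryote"] * len(euk), index=all_tax.index
        ),
    )
    truth = pd.DataFrame(truth_rows).set_index("sample_id").join(samples)
    return table, truth


def estimate_riverine_fraction(table: OtuTable, riverine_otus) -> pd.Series:
    """Estimate each sample's riverine mixing weight from its profile.

    Copy-number-corrected relative abundance summed over the riverine
    endmember's OTUs — the natural plug-in estimator of w.
    """
    from .diversity import copy_number_correct

    prok = table.prokaryotes()
    rel = prok.relative_abundance()
    corrected = copy_number_correct(rel, prok.copy_number.reindex(rel.columns))
    cols = [o for o in riverine_otus if o in corrected.columns]
    return corrected[cols].sum(axis=1)


DEFAULT_GUIDELINES = {"SS": 0.0, "CHLA": 0.0, "PN": 0.0, "PP": 0.0}


def water_quality_index(env: pd.DataFrame, guidelines: dict | None = None) -> pd.Series:
    """Simplified guideline-ratio water-quality score in [-1, +1].

    Each of the four indicator concentrations (suspended solids,
    chlorophyll a, particulate nitrogen, particulate phosphorus) scores
    +1 when at or below its guideline and -1 above it; the index is the
    mean of the four scores (+1 very good ... -1 poor).  Missing
    indicators raise — no silent imputation.
    """
    guidelines = guidelines or DEFAULT_GUIDELINES
    missing = [k for k in guidelines if k not in env.columns]
    if missing:
        raise ConfigError(f"missing water-quality indicators: {missing}")
    scores = []
    for name, limit in guidelines.items():
        col = env[name]
        if col.isna().any():
            raise ConfigError(f"indicator {name!r} has missing values")
        scores.append(np.where(col <= limit, 1.0, -1.0))
    return pd.Series(np.mean(scores, axis=0), index=env.index, name="water_qual_idx")


def rolling_7day_mean(series: pd.Series, at: date) -> tuple[float, int]:
    """Mean over the 7 calendar days strictly before ``at``.

    Returns (mean, number of days with observations).  Missing days are
    simply absent from the mean; an empty window raises.
    """
    s = series.copy()
    s.index = pd.DatetimeIndex(s.index)
    end = pd.Timestamp(at)
    window = s.loc[(s.index >= end - pd.Timedelta(days=7)) & (s.index < end)].dropna()
    if window.empty:
        raise ConfigError(f"no observations in the 7 days before {at}")
    return float(window.mean()), int(window.size)
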