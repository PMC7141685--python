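"""Published survey inputs for the three Guatemalan study sites.

The one-square-kilometre sites -- La Romana, Sabaneta and the Poptún urban
site (Petén department, Guatemala) -- were surveyed with a door-to-door
collaring campaign, four foot-patrol transect rounds each, simultaneous UAV
flights, and (for the two villages) a pre-existing human and owned-dog
census. The printed survey-design numbers collected here are the inputs
the estimators and the capture-recapture priors are built from; nothing in
this module is a model output.

Note the Poptún collared-dog total is reported inconsistently at source
(117 in prose, 118 in the prior table); the table value is used.
"""

from __future__ import annotations

from .estimators import DetectionRecord, SiteCensus, TransectCountRecord
from .model import CRPriorSet
from .priors import (
    DiscreteUniformPrior,
    LogNormalPrior,
    MarkingSummary,
    UniformPrior,
    owned_count_prior,
    recapture_prior,
)

SITES = ("la_romana", "sabaneta", "poptun")

#: Marking campaign totals: dogs collared (Mc), collars lost (Ml),
#: transect rounds (T).
MARKING = {
    "la_romana": MarkingSummary(n_collared=61, n_lost=3, n_transects=4),
    "sabaneta": MarkingSummary(n_collared=125, n_lost=2, n_transects=4),
    "poptun": MarkingSummary(n_collared=118, n_lost=4, n_transects=4),
}

#: (min, max) bounds of the three recapture-probability components.
RECAPTURE_COMPONENTS = {
    "la_romana": {"coverage": (0.44, 1.00), "encounter": (0.70, 0.90), "record": (0.90, 0.99)},
    "sabaneta": {"coverage": (0.23, 0.80), "encounter": (0.70, 0.90), "record": (0.90, 0.99)},
    "poptun": {"coverage": (0.26, 0.76), "encounter": (0.70, 0.90), "record": (0.90, 0.99)},
}

#: Elicited confinement-probability bounds (weighted over roaming categories).
CONFINEMENT_BOUNDS = {
    "la_romana": (0.133, 0.142),
    "sabaneta": (0.157, 0.157),
    "poptun": (0.293, 0.320),
}

#: Fitted log-normal ownerless:owned ratio parameters (mu, precision tau).
RATIO_PARAMS = {
    "la_romana": (-6.57, 5.24),
    "sabaneta": (-7.71, 4.97),
    "poptun": (-7.67, 4.98),
}

OWNED_CAP = 1000

#: Human and owned-dog census (no census was taken in the Poptún site).
CENSUS = {
    "la_romana": SiteCensus("la_romana", humans=485, owned_dogs=110),
    "sabaneta": SiteCensus("sabaneta", humans=804, owned_dogs=289),
}

#: Humans-per-dog ratio used by the national rabies vaccination campaign.
NATIONAL_HUMAN_DOG_RATIO = 5.0

#: Dogs counted per transect round, UAV flights vs ground transect walks.
#: The third UAV flight in Poptún was rained out.
TRANSECT_COUNTS = [
    TransectCountRecord("la_romana", "uav", 1, 0),
    TransectCountRecord("la_romana", "uav", 2, 0),
    TransectCountRecord("la_romana", "uav", 3, 3),
    TransectCountRecord("la_romana", "uav", 4, 8),
    TransectCountRecord("la_romana", "ground", 1, 26),
    TransectCountRecord("la_romana", "ground", 2, 29),
    TransectCountRecord("la_romana", "ground", 3, 33),
    TransectCountRecord("la_romana", "ground", 4, 24),
    TransectCountRecord("sabaneta", "uav", 1, 31),
    TransectCountRecord("sabaneta", "uav", 2, 2),
    TransectCountRecord("sabaneta", "uav", 3, 35),
    TransectCountRecord("sabaneta", "uav", 4, 28),
    TransectCountRecord("sabaneta", "ground", 1, 94),
    TransectCountRecord("sabaneta", "ground", 2, 80),
    TransectCountRecord("sabaneta", "ground", 3, 88),
    TransectCountRecord("sabaneta", "ground", 4, 92),
    TransectCountRecord("poptun", "uav", 1, 33),
    TransectCountRecord("poptun", "uav", 2, 13),
    TransectCountRecord("poptun", "uav", 4, 25),
    TransectCountRecord("poptun", "ground", 1, 55),
    TransectCountRecord("poptun", "ground", 2, 69),
    TransectCountRecord("poptun", "ground", 3, 51),
    TransectCountRecord("poptun", "ground", 4, 36),
]

#: Fraction of UAV-detected dogs per land-cover class and the fraction of
#: the site each class covers; counts are the published percentages applied
#: to the site's UAV total (11 / 96 / 71 dogs).
LAND_COVER_FRACTIONS = {
    "la_romana": {"yards": (0.91, 0.31), "roads": (0.00, 0.02), "fields_forest": (0.09, 0.16)},
    "sabaneta": {"yards": (0.64, 0.68), "roads": (0.36, 0.05), "fields_forest": (0.00, 0.28)},
    "poptun": {"yards": (0.69, 0.83), "roads": (0.31, 0.17), "fields_forest": (0.00, 0.00)},
}


def site_recapture_prior(site: str, report_decimals: int | None = 2) -> UniformPrior:
    """Recapture prior from the site's printed coverage/encounter/record bounds."""
    comp = RECAPTURE_COMPONENTS[site]
    return recapture_prior(
        *comp["coverage"], *comp["encounter"], *comp["record"],
        report_decimals=report_decimals,
    )


def site_priors(site: str) -> CRPriorSet:
    """The full prior set for one study site, as published."""
    if site not in SITES:
        raise KeyError(f"unknown site {site!r}; expected one of {SITES}")
    mu, tau = RATIO_PARAMS[site]
    return CRPriorSet(
        recapture=site_recapture_prior(site),
        confinement=UniformPrior(*CONFINEMENT_BOUNDS[site]),
        ratio=LogNormalPrior(mu, tau),
        owned=owned_count_prior(MARKING[site].n_collared, OWNED_CAP),
    )


def site_detection_records(site: str) -> list[DetectionRecord]:
    """Land-cover detection records for one site (counts reconstituted from
    the published percentages and UAV totals)."""
    from .estimators import aggregate_transect_counts

    totals = aggregate_transect_counts(
        [r for r in TRANSECT_COUNTS if r.site == site and r.method == "uav"]
    )
    total = int(totals[(site, "uav")])
    return [
        DetectionRecord(site, cover, round(frac * total), area)
        for cover, (frac, area) in LAND_COVER_FRACTIONS[site].items()
    ]
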