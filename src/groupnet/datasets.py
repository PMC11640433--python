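"""Packaged reference data.

* the roster of the Living Links mixed-species colony (two groups of
  tufted capuchins and squirrel monkeys: West 18 + 9, East 17 + 17),
  used as the canonical roster fixture and as the default composition
  for synthetic sampling;
* the summary network metrics published for that colony (per-species
  means and SDs, network densities, mean association rates, observed
  species differences), used as inputs for internal-consistency checks
  — e.g. the size-weighted mean degree of a group must reproduce its
  printed density via mean_degree / (n - 1).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .observation import IndividualRecord, read_roster

#: published overall network densities per group
PUBLISHED_DENSITY = {"West": 0.590, "East": 0.733}

#: published mean (SD) association rate over all dyads per group
PUBLISHED_MEAN_SRI = {"West": (0.032, 0.056), "East": (0.022, 0.04)}

#: published observed species differences (capuchin - squirrel monkey)
#: per group and metric, from the permutation t-tests
PUBLISHED_OBSERVED_DIFFERENCES = {
    ("West", "eigenvector"): 0.463,
    ("East", "eigenvector"): 0.387,
    ("West", "degree"): 7.333,
    ("East", "degree"): -1.529,
    ("West", "betweenness"): -11.364,
    ("East", "betweenness"): 4.855,
    ("West", "clustering"): 0.115,
    ("East", "clustering"): -0.001,
}

#: published per-species network metric means (SD), rows (group, species)
_PUBLISHED_SPECIES_METRICS = [
    # group, species, n, degree, eigenvector, betweenness, clustering
    ("West", "capuchin", 18, 17.78, 1.31, 0.49, 0.33, 18.08, 1.31, 0.88, 0.09),
    ("West", "squirrel_monkey", 9, 10.44, 2.40, 0.02, 0.007, 29.44, 24.50, 0.77, 0.19),
    ("East", "capuchin", 17, 23.41, 3.36, 0.48, 0.31, 17.79, 9.34, 0.79, 0.03),
    ("East", "squirrel_monkey", 17, 24.94, 4.59, 0.09, 0.04, 12.93, 13.05, 0.79, 0.06),
]

#: focal observation design: follows per individual x minutes per follow
FOLLOWS_PER_INDIVIDUAL = 18
SAMPLES_PER_FOLLOW = 10


def living_links_roster() -> list[IndividualRecord]:
    """The packaged colony roster (61 individuals across West and East)."""
    path = resources.files("groupnet.data") / "living_links_roster.csv"
    with resources.as_file(path) as p:
        return read_roster(p)


def published_species_metrics() -> pd.DataFrame:
    """Published per-species metric means and SDs, indexed (group, species)."""
    rows = []
    for (g, s, n, dm, dsd, em, esd, bm, bsd, cm, csd) in _PUBLISHED_SPECIES_METRICS:
        rows.append(
            {
                "group": g,
                "species": s,
                "n": n,
                "degree_mean": dm,
                "degree_sd": dsd,
                "eigenvector_mean": em,
                "eigenvector_sd": esd,
                "betweenness_mean": bm,
                "betweenness_sd": bsd,
                "clustering_mean": cm,
                "clustering_sd": csd,
            }
        )
    return pd.DataFrame(rows).set_index(["group", "species"])


def implied_density(group: str) -> float:
    """Density implied by the published per-species degree means.

    The mean degree over all nodes equals density x (n - 1), so the
    size-weighted mean of the published species degree means, divided by
    (n - 1), must reproduce the published density — an internal
    consistency check on the published table.
    """
    table = published_species_metrics().loc[group]
    n_total = int(table["n"].sum())
    weighted = float((table["n"] * table["degree_mean"]).sum()) / n_total
    return weighted / (n_total - 1)
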