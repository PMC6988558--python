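"""Default covariate catalog for North San Francisco Bay trap surveys.

Covariates are grouped into the seven sets used to define model variants:

* C1 trap design (site, year, session, trap layout, trap position)
* C2 location (latitude, longitude)
* C3 vegetation & cover, dominant plant only
* C4 vegetation & cover, top three plants (superset of C3)
* C5 elevation and tidal datums
* C6 distances to natural/anthropogenic features
* C7 marsh patch size
"""

from __future__ import annotations

from .case_data import CovariateDef

#: Trap-layout vocabulary.
LAYOUTS = ("grid", "transect", "random")

#: Ground-cover categories used for the dominant-plant covariates.
COVER_CLASSES = ("pickleweed", "bare_ground", "saltgrass", "alkali_heath", "other")


def default_catalog() -> list[CovariateDef]:
    """The full covariate catalog, in canonical (catalog) order."""
    c: list[CovariateDef] = []

    def add(name, description, units, kind, sets, labels=None):
        c.append(CovariateDef(name, description, units, kind, frozenset(sets), labels))

    # C1 — trap sampling design
    add("site", "study site (marsh) identifier", "categorical", "categorical", {"C1"})
    add("year", "survey year", "categorical", "categorical", {"C1"})
    add("session", "trapping session within the year", "categorical", "categorical", {"C1"})
    add("layout", "trap layout pattern", "categorical", "categorical", {"C1"}, LAYOUTS)
    add("trap_position", "trap position identifier within the site", "categorical",
        "categorical", {"C1"})
    # C2 — location
    add("latitude", "trap latitude (WGS84)", "degrees", "continuous", {"C2"})
    add("longitude", "trap longitude (WGS84)", "degrees", "continuous", {"C2"})
    # C3 — dominant plant (also part of C4)
    add("P1_Species", "most dominant cover category at the trap", "categorical",
        "categorical", {"C3", "C4"}, COVER_CLASSES)
    add("P1_V_PERC", "percent cover of most dominant plant species", "%",
        "continuous", {"C3", "C4"})
    add("P1_V1_MAX", "maximum height of most dominant plant species", "cm",
        "continuous", {"C3", "C4"})
    add("P1_V1_AVG", "average height of most dominant plant species", "cm",
        "continuous", {"C3", "C4"})
    # C4 — second and third most dominant plants
    for k in (2, 3):
        add(f"P{k}_Species", f"cover category ranked {k} at the trap", "categorical",
            "categorical", {"C4"}, COVER_CLASSES)
        add(f"P{k}_V_PERC", f"percent cover of plant ranked {k}", "%", "continuous", {"C4"})
        add(f"P{k}_V1_MAX", f"maximum height of plant ranked {k}", "cm", "continuous", {"C4"})
        add(f"P{k}_V1_AVG", f"average height of plant ranked {k}", "cm", "continuous", {"C4"})
    # C5 — elevation / tidal datums
    add("Marsh_Elev", "marsh elevation at the trap location (from DEM)", "cm",
        "continuous", {"C5"})
    add("MHW", "mean high water level", "m", "continuous", {"C5"})
    add("MHHW", "mean higher high water level", "m", "continuous", {"C5"})
    add("Elev_MHW", "trap elevation relative to mean high water", "m", "continuous", {"C5"})
    add("Elev_MHHW", "trap elevation relative to mean higher high water", "m",
        "continuous", {"C5"})
    # C6 — distances
    add("Dist_Levee", "distance to closest levee", "m", "continuous", {"C6"})
    add("Dist_Water", "distance to closest water", "m", "continuous", {"C6"})
    add("Dist_Bay", "distance to the bay", "m", "continuous", {"C6"})
    add("Dist_Urban", "distance to closest urban area", "m", "continuous", {"C6"})
    add("Dist_Ag", "distance to closest agriculture", "m", "continuous", {"C6"})
    add("Dist_Road", "distance to closest paved road", "m", "continuous", {"C6"})
    # C7 — patch size
    add("Patch_Size", "continuous marsh patch size (not impeded by barriers, "
        "channels >3 m, or levees)", "ha", "continuous", {"C7"})
    add("Patch_Size_Expanded", "continuous marsh patch size (not impeded by "
        "barriers or channels >3 m)", "ha", "continuous", {"C7"})
    return c


#: The 13 continuous elevation / distance / patch covariates entering the
#: pre-model Pearson correlation screen (vegetation covariates are excluded
#: from screening because of their sparsity).
SCREENED_COVARIATES = (
    "Marsh_Elev", "MHW", "MHHW", "Elev_MHW", "Elev_MHHW",
    "Dist_Levee", "Dist_Water", "Dist_Bay", "Dist_Urban", "Dist_Ag", "Dist_Road",
    "Patch_Size", "Patch_Size_Expanded",
)

#: The 16 covariates of the RERA-vs-MICA habitat comparison table
#: (13 screened covariates plus the dominant-plant cover/height metrics).
COMPARISON_COVARIATES = (
    "Marsh_Elev", "P1_V_PERC", "P1_V1_MAX", "P1_V1_AVG",
    "MHW", "Elev_MHW", "MHHW", "Elev_MHHW",
    "Dist_Levee", "Dist_Water", "Dist_Bay", "Dist_Urban", "Dist_Ag", "Dist_Road",
    "Patch_Size", "Patch_Size_Expanded",
)
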