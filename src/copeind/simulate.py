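"""Synthetic copepod community generator with planted indicator species.

The generator emulates a late-autumn surface survey off northeastern
Taiwan: ~25 stations in three water masses (monsoon-derived cold water "A",
mixed water "B", Kuroshio intrusion water "C"), four hydrographic
variables drawn normally from group-specific profiles, and a right-skewed
(lognormal) site-by-species abundance matrix whose station totals sit in
the few-hundred-to-1500 ind m^-3 band.

Each planted indicator targets one group with a chosen specificity ``A*``
and fidelity ``B*``: it occurs at each target-group station with
probability ``B*`` (lognormal abundance around its mean when present) and
its expected mean abundance in the other groups is set so that the
*expected* specificity equals ``A*``; off-group occupancy is partial.
Background taxa are drawn independently of the grouping, with a heavy-
tailed rank-abundance distribution and a per-station lognormal factor that
produces realistic variation in station totals.

A fixed integer seed drives a single :func:`numpy.random.default_rng`
generator, so identical seeds give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, EnvTable, GroupPartition, TaxonMeta, ENV_COLUMNS
from .errors import DesignError
from . import indval as _indval


# ---------------------------------------------------------------------------
# design


#: per-group environmental means and SDs (temperature degC, salinity PSU,
#: dissolved oxygen mg/L, pH) for the three water masses the generator
#: emulates: monsoon-derived cold water (A), mixed water (B), Kuroshio
#: intrusion water (C).
DEFAULT_ENV_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "A": {"temperature": (22.78, 0.58), "salinity": (34.19, 0.10),
          "dissolved_oxygen": (7.07, 0.08), "pH": (8.33, 0.03)},
    "B": {"temperature": (24.31, 0.37), "salinity": (34.17, 0.03),
          "dissolved_oxygen": (6.89, 0.04), "pH": (8.36, 0.02)},
    "C": {"temperature": (26.52, 0.63), "salinity": (34.27, 0.04),
          "dissolved_oxygen": (6.63, 0.07), "pH": (8.39, 0.01)},
}


@dataclasses.dataclass(frozen=True)
class PlantedIndicator:
    """A taxon planted with known specificity/fidelity for one group."""

    taxon_id: str
    group: str
    specificity: float  # target A* in [0, 1]
    fidelity: float  # target B* in [0, 1]
    mean_abundance: float  # mean abundance at occupied target-group stations
    order: str = "Calanoida"

    def __post_init__(self) -> None:
        if not (0.0 <= self.specificity <= 1.0):
            raise DesignError(
                f"{self.taxon_id}: specificity must lie in [0, 1]"
            )
        if not (0.0 <= self.fidelity <= 1.0):
            raise DesignError(f"{self.taxon_id}: fidelity must lie in [0, 1]")
        if self.mean_abundance < 0:
            raise DesignError(f"{self.taxon_id}: mean abundance must be >= 0")
        if (
            self.specificity == 0.0
            and self.fidelity > 0.0
            and self.mean_abundance > 0.0
        ):
            raise DesignError(
                f"{self.taxon_id}: specificity 0 with positive in-group "
                "abundance would need infinite off-group abundance"
            )


#: default planted indicators, patterned on the indicator species of the
#: emulated survey (specificity/fidelity/abundance in the Table-2 range)
DEFAULT_PLANTED: tuple[PlantedIndicator, ...] = (
    PlantedIndicator("Temora turbinata", "A", 0.829, 0.833, 93.9, "Calanoida"),
    PlantedIndicator("Canthocalanus pauper", "A", 0.653, 1.0, 60.9, "Calanoida"),
    PlantedIndicator("Calanopia elliptica", "A", 0.807, 0.833, 10.1, "Calanoida"),
    PlantedIndicator("Paracalanus aculeatus", "B", 0.528, 1.0, 217.1, "Calanoida"),
    PlantedIndicator("Oncaea clevei", "B", 0.552, 1.0, 21.3, "Poecilostomatoida"),
    PlantedIndicator("Paracandacia truncata", "B", 0.849, 0.818, 1.44, "Calanoida"),
    PlantedIndicator("Farranula concinna", "C", 0.943, 1.0, 33.3, "Poecilostomatoida"),
    PlantedIndicator("Copilia mirabilis", "C", 0.920, 1.0, 3.09, "Poecilostomatoida"),
    PlantedIndicator("Candacia aethiopica", "C", 0.762, 0.875, 1.90, "Calanoida"),
)

#: copepodite categories (juveniles; never counted as species)
_COPEPODITE_TAXA: tuple[tuple[str, str], ...] = (
    ("Calanoid copepodites", "Calanoida"),
    ("Euchaeta (copepodites)", "Calanoida"),
    ("Candacia (copepodites)", "Calanoida"),
    ("Centropages (copepodites)", "Calanoida"),
    ("Temora (copepodites)", "Calanoida"),
    ("Acartia (copepodites)", "Calanoida"),
    ("Clausocalanus (copepodites)", "Calanoida"),
    ("Paracalanus (copepodites)", "Calanoida"),
    ("Oncaea (copepodites)", "Poecilostomatoida"),
    ("Corycaeus (copepodites)", "Poecilostomatoida"),
    ("Farranula (copepodites)", "Poecilostomatoida"),
    ("Oithona (copepodites)", "Cyclopoida"),
    ("Macrosetella (copepodites)", "Harpacticoida"),
)

#: background species counts per order, chosen so the default design totals
#: 108 species: 68 Calanoida (62.96%), 33 Poecilostomatoida (30.56%) and 7
#: Cyclopoida+Harpacticoida (6.48%) including the planted species above.
_BACKGROUND_SPECIES_COUNTS: dict[str, int] = {
    "Calanoida": 62,
    "Poecilostomatoida": 30,
    "Cyclopoida": 4,
    "Harpacticoida": 3,
}


@dataclasses.dataclass(frozen=True)
class SyntheticDesign:
    """Full description of one synthetic survey."""

    group_sizes: tuple[int, ...] = (6, 11, 8)
    group_labels: tuple[str, ...] = ("A", "B", "C")
    env_profiles: Mapping[str, Mapping[str, tuple[float, float]]] = (
        dataclasses.field(default_factory=lambda: DEFAULT_ENV_PROFILES)
    )
    planted_indicators: tuple[PlantedIndicator, ...] = DEFAULT_PLANTED
    background_species_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: _BACKGROUND_SPECIES_COUNTS
    )
    total_mean_abundance: float = 774.24  # target survey-wide mean, ind m^-3
    dominant_copepodite_mean: float = 217.24  # "Calanoid copepodites"
    rank_abundance_sigma: float = 1.6  # lognormal spread of background means
    abundance_sigma: float = 0.6  # per-station lognormal noise (log scale)
    station_sigma: float = 0.25  # station-level lognormal factor (log scale)
    off_group_occupancy: float = 0.7  # planted presence prob. outside target
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.group_labels):
            raise DesignError("group_sizes and group_labels must align")
        if any(n < 2 for n in self.group_sizes):
            raise DesignError("every group needs at least 2 stations")
        if len(set(self.group_labels)) != len(self.group_labels):
            raise DesignError("group labels must be unique")
        for label in self.group_labels:
            if label not in self.env_profiles:
                raise DesignError(f"no environmental profile for group {label!r}")
            for var in ENV_COLUMNS:
                mean, sd = self.env_profiles[label][var]
                if sd < 0:
                    raise DesignError(f"negative SD for {var} in group {label!r}")
        for p in self.planted_indicators:
            if p.group not in self.group_labels:
                raise DesignError(
                    f"planted taxon {p.taxon_id!r} targets unknown group "
                    f"{p.group!r}"
                )
        if not (0.0 < self.off_group_occupancy <= 1.0):
            raise DesignError("off_group_occupancy must lie in (0, 1]")
        for field in ("rank_abundance_sigma", "abundance_sigma", "station_sigma"):
            if getattr(self, field) < 0:
                raise DesignError(f"{field} must be >= 0")

    @property
    def n_stations(self) -> int:
        return int(sum(self.group_sizes))


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, recomputed from the emitted
    matrix with the IndVal machinery itself."""

    partition: GroupPartition
    planted: pd.DataFrame  # index taxon; target group, A*, B*, expected and
    # realized A / B / IndVal

    def to_json(self, path: str | Path) -> None:
        payload = {
            "partition": dict(self.partition.labels),
            "planted": self.planted.reset_index().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _lognormal_mean(
    rng: np.random.Generator, mean: float, sigma: float, size: int
) -> np.ndarray:
    """Lognormal draws with expectation ``mean``."""
    if mean <= 0 or size == 0:
        return np.zeros(size)
    if sigma == 0:
        return np.full(size, mean)
    return rng.lognormal(np.log(mean) - sigma**2 / 2.0, sigma, size)


def _planted_group_means(
    design: SyntheticDesign, p: PlantedIndicator
) -> dict[str, float]:
    """Expected per-group mean abundance of a planted taxon."""
    mu_target = p.fidelity * p.mean_abundance
    others = [g for g in design.group_labels if g != p.group]
    if mu_target == 0.0 or p.specificity == 1.0:
        off = 0.0
    else:
        off = mu_target * (1.0 - p.specificity) / p.specificity / len(others)
    means = {g: off for g in others}
    means[p.group] = mu_target
    return means


def generate(
    design: SyntheticDesign,
) -> tuple[AbundanceMatrix, EnvTable, TaxonMeta, GroundTruth]:
    """Draw one synthetic survey from ``design`` (deterministic per seed)."""
    rng = np.random.default_rng(design.seed)
    labels = design.group_labels
    station_ids: list[str] = []
    station_groups: list[str] = []
    for label, size in zip(labels, design.group_sizes):
        for _ in range(size):
            station_ids.append(f"St{len(station_ids) + 1:02d}")
            station_groups.append(label)
    n = len(station_ids)
    groups = pd.Series(station_groups, index=station_ids)
    partition = GroupPartition(groups)

    # --- environment -------------------------------------------------------
    env_rows = np.empty((n, len(ENV_COLUMNS)))
    for i, g in enumerate(station_groups):
        for j, var in enumerate(ENV_COLUMNS):
            mean, sd = design.env_profiles[g][var]
            env_rows[i, j] = rng.normal(mean, sd)
    env = EnvTable(pd.DataFrame(env_rows, index=station_ids,
                                columns=list(ENV_COLUMNS)))

    # --- taxon roster ------------------------------------------------------
    taxa: list[str] = []
    orders: list[str] = []
    copepodite: list[bool] = []
    for p in design.planted_indicators:
        taxa.append(p.taxon_id)
        orders.append(p.order)
        copepodite.append(False)
    background_names: list[str] = []
    for order, count in design.background_species_counts.items():
        stem = order.removesuffix("a")  # Calanoida -> Calanoid
        for i in range(count):
            name = f"{stem} sp. {i + 1:02d}"
            taxa.append(name)
            orders.append(order)
            copepodite.append(False)
            background_names.append(name)
    for name, order in _COPEPODITE_TAXA:
        taxa.append(name)
        orders.append(order)
        copepodite.append(True)
        if name != "Calanoid copepodites":
            background_names.append(name)
    meta = TaxonMeta(
        pd.DataFrame(
            {"order": orders, "is_copepodite": np.array(copepodite)},
            index=pd.Index(taxa, name="taxon"),
        )
    )

    # --- expected mean abundances -----------------------------------------
    sizes = np.asarray(design.group_sizes, dtype=float)
    planted_overall = 0.0
    planted_means: dict[str, dict[str, float]] = {}
    for p in design.planted_indicators:
        gm = _planted_group_means(design, p)
        planted_means[p.taxon_id] = gm
        planted_overall += sum(
            gm[g] * sz for g, sz in zip(labels, sizes)
        ) / sizes.sum()
    budget = (
        design.total_mean_abundance
        - design.dominant_copepodite_mean
        - planted_overall
    )
    if budget <= 0:
        raise DesignError(
            "planted taxa and the dominant copepodite category already "
            f"exceed the target total mean abundance "
            f"({design.total_mean_abundance} ind m^-3)"
        )
    rel = rng.lognormal(0.0, design.rank_abundance_sigma, len(background_names))
    background_mean = dict(
        zip(background_names, budget * rel / rel.sum())
    )
    background_mean["Calanoid copepodites"] = design.dominant_copepodite_mean

    # --- abundance draws ---------------------------------------------------
    station_factor = (
        _lognormal_mean(rng, 1.0, design.station_sigma, n)
        if design.station_sigma > 0
        else np.ones(n)
    )
    group_index = {g: np.array([s == g for s in station_groups]) for g in labels}
    x = np.zeros((n, len(taxa)))
    col = {t: i for i, t in enumerate(taxa)}

    for p in design.planted_indicators:
        gm = planted_means[p.taxon_id]
        for g in labels:
            mask = group_index[g]
            m = mask.sum()
            if g == p.group:
                occ_p, mean_present = p.fidelity, p.mean_abundance
            else:
                occ_p = design.off_group_occupancy
                mean_present = gm[g] / occ_p
            if mean_present == 0.0 or occ_p == 0.0:
                continue
            present = rng.random(int(m)) < occ_p
            draws = _lognormal_mean(
                rng, mean_present, design.abundance_sigma, int(present.sum())
            )
            vals = np.zeros(int(m))
            vals[present] = draws
            x[mask, col[p.taxon_id]] = vals

    for name in ["Calanoid copepodites"] + background_names:
        mean = background_mean[name]
        if mean <= 0:
            continue
        # occupancy rises with abundance: dominants near 100%, rare taxa low
        occ_p = float(np.clip(0.6 + 0.2 * np.log10(mean + 1e-12), 0.2, 1.0))
        present = rng.random(n) < occ_p
        draws = _lognormal_mean(
            rng, mean / occ_p, design.abundance_sigma, int(present.sum())
        )
        vals = np.zeros(n)
        vals[present] = draws
        x[:, col[name]] = vals

    x *= station_factor[:, None]
    abund = AbundanceMatrix(
        pd.DataFrame(x, index=pd.Index(station_ids, name="station"),
                     columns=taxa)
    )

    # --- ground truth ------------------------------------------------------
    table = _indval.indval_table(abund, partition)
    rows = {}
    for p in design.planted_indicators:
        sub = table[(table["taxon"] == p.taxon_id) & (table["group"] == p.group)]
        rec = sub.iloc[0]
        rows[p.taxon_id] = {
            "group": p.group,
            "target_specificity": p.specificity,
            "target_fidelity": p.fidelity,
            "expected_indval": 100.0 * p.specificity * p.fidelity,
            "realized_specificity": float(rec["specificity"]),
            "realized_fidelity": float(rec["fidelity"]),
            "realized_indval": float(rec["indval"]),
        }
    planted = pd.DataFrame.from_dict(rows, orient="index")
    planted.index.name = "taxon"
    truth = GroundTruth(partition=partition, planted=planted)
    return abund, env, meta, truth
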