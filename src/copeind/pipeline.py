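"""End-to-end analysis runner.

Executes the survey workflow in its canonical order — community statistics,
environmental clustering, ANOVA/Tukey on station totals, indicator-value
analysis, DCA gate and RDA — writing every stage's table as CSV plus a
machine-readable ``summary.json`` and a run log.  A failure in any stage
aborts with a stage-tagged error; tables already written are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .clustering import EnvClustering
from .community import dominance_table, dominant_taxa, order_composition
from .datatypes import AbundanceMatrix, EnvTable, TaxonMeta, validate_joint
from .errors import StageError, ValidationError
from .group_tests import AbundanceAnova, station_totals
from .indval import IndicatorValueModel
from .io import read_abundance, read_env, read_taxa, write_partition
from .ordination import DCA, RDA

log = logging.getLogger("copeind")


@dataclasses.dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    abundance: str
    environment: str
    taxa: str
    output_dir: str = "copeind_results"
    k: int = 3
    ra_threshold: float = 2.0  # dominance cut, % relative abundance
    indval_threshold: float = 50.0  # indicator selection cut, %
    permutations: int = 999  # SIMPROF and IndVal permutation count
    standardize_env: bool = False
    hellinger: bool = False
    dca_segments: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not (0.0 < self.ra_threshold <= 100.0):
            raise ValidationError("ra_threshold must lie in (0, 100]")
        if not (0.0 < self.indval_threshold < 100.0):
            raise ValidationError("indval_threshold must lie in (0, 100)")
        if self.permutations < 0:
            raise ValidationError("permutations must be >= 0")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a flat key/value TOML file; keyword overrides win."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every analysis stage; returns (and writes) the summary report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict[str, Any] = {"version": __version__, "seed": config.seed,
                              "config": dataclasses.asdict(config)}

    def stage(name: str):
        log.info("stage: %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    try:
        with stage("read"):
            abund = read_abundance(config.abundance)
            env = read_env(config.environment)
            taxa = read_taxa(config.taxa)
            validate_joint(abund=abund, env=env, taxa=taxa)
            log.info("read %d stations, %d taxa", abund.n_stations, abund.n_taxa)

        with stage("community"):
            dom = dominance_table(abund)
            dom.per_taxon.to_csv(out / "dominance.csv")
            comp = order_composition(abund, taxa)
            comp.to_csv(out / "order_composition.csv")
            dominants = dominant_taxa(dom, ra_threshold=config.ra_threshold)
            dominants.to_csv(out / "dominant_taxa.csv")
            report["community"] = {
                "total_mean_abundance": dom.total_mean_abundance,
                "n_dominant_taxa": int(len(dominants)),
            }

        with stage("cluster"):
            if config.k < 1:
                raise ValidationError("k must be >= 1")
            clust = EnvClustering(env, standardize=config.standardize_env).fit(
                k=config.k,
                simprof_permutations=config.permutations,
                seed=config.seed,
            )
            write_partition(clust.partition, out / "partition.csv")
            clust.group_similarity.to_csv(out / "group_similarity.csv")
            clust.simprof.to_csv(out / "simprof.csv")
            (out / "dendrogram.nwk").write_text(clust.to_newick() + "\n")
            report["cluster"] = {
                "group_sizes": {k: int(v)
                                for k, v in clust.partition.group_sizes.items()},
                "group_similarity": clust.group_similarity["mean_similarity"]
                .round(4).to_dict(),
                "simprof_p": {g: (None if pd.isna(p) else round(float(p), 6))
                              for g, p in clust.simprof["p_value"].items()},
            }
            partition = clust.partition

        with stage("anova"):
            totals = station_totals(abund)
            totals.rename_axis("station").to_csv(out / "station_totals.csv")
            if partition.n_groups < 2:
                # nothing to compare; the indval stage raises the error the
                # user needs to see (both require >= 2 groups)
                log.warning("anova skipped: only %d group", partition.n_groups)
                report["anova"] = None
            else:
                anova = AbundanceAnova(totals, partition).fit()
                anova.tukey.to_csv(out / "tukey.csv", index=False)
                report["anova"] = {
                    "f": anova.f_statistic,
                    "df": [anova.df_between, anova.df_within],
                    "p": anova.p_value,
                }

        with stage("indval"):
            if partition.n_groups < 2:
                raise ValidationError(
                    "indicator-value analysis needs at least 2 groups; "
                    f"clustering produced {partition.n_groups} (k={config.k})"
                )
            iv = IndicatorValueModel(abund, partition).fit(
                permutations=config.permutations, seed=config.seed
            )
            iv.table.to_csv(out / "indval.csv", index=False)
            if iv.pvalues is not None:
                iv.pvalues.to_csv(out / "indval_pvalues.csv", index=False)
            selection = iv.select(threshold=config.indval_threshold)
            selection.to_csv(out / "indicators.csv", index=False)
            report["indval"] = {
                "threshold": config.indval_threshold,
                "indicators": {
                    g: sub["taxon"].tolist()
                    for g, sub in selection.groupby("group")
                },
            }

        with stage("ordination"):
            dom_matrix = abund.select_taxa(list(dominants.index))
            dca = DCA(dom_matrix.data, segments=config.dca_segments).fit()
            rda_res = RDA(dom_matrix.data, env.data.loc[dom_matrix.data.index],
                          hellinger=config.hellinger).fit()
            pd.DataFrame({"axis_length": dca.axis_lengths},
                         index=[f"DCA{i+1}" for i in
                                range(len(dca.axis_lengths))]).to_csv(
                out / "dca_axis_lengths.csv")
            rda_res.eigenvalues.to_csv(out / "rda_eigenvalues.csv")
            rda_res.site_scores.to_csv(out / "rda_site_scores.csv")
            rda_res.species_scores.to_csv(out / "rda_species_scores.csv")
            rda_res.biplot_scores.to_csv(out / "rda_biplot_scores.csv")
            report["ordination"] = {
                "dca_first_axis_length": dca.first_axis_length,
                "linear_gate": bool(dca.gate()),
                "proportion_constrained": rda_res.proportion_constrained,
            }

        with stage("report"):
            (out / "summary.json").write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n"
            )
        log.info("pipeline complete: %s", out)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
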