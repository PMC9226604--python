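"""End-to-end orchestration: filters -> responses -> diversity -> networks
-> null ensembles -> sub-network linkage.

Every stage writes plain TSV/CSV/JSON files into the output directory so
any stage can be re-run or audited standalone; a single top-level seed
deterministically derives one independent random stream per stage, so a
re-run with the same config and seed reproduces every output
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import alpha_over_rarefactions, bray_curtis, permanova, rarefy_once, within_among_test
from .io_tables import read_otu_table, read_traits
from .linkage import abundance_response_screen, link_regression, subnetwork_property_table
from .network import (
    build_networks_by_group,
    compare_to_null,
    er_null_ensemble,
    network_properties,
)
from .response import compute_responses, test_nonzero, two_way_anova

__all__ = ["PipelineConfig", "ReportBundle", "StageError", "run_pipeline", "render_report"]

# Table-3-shaped display header for the property panel
PANEL_DISPLAY = [
    ("node", "Node"),
    ("edge", "Edge"),
    ("edges_per_node", "Edges per node"),
    ("average_degree", "Average degree"),
    ("average_clustering_coefficient", "Average clustering coefficient"),
    ("average_path_distance", "Average path distance"),
    ("density", "Density"),
    ("diameter", "Diameter"),
    ("connectedness", "Connectedness"),
    ("modularity", "Modularity"),
    ("module_number", "Module number"),
    ("proportion_positive", "Proportion of positive correlations"),
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    otu: str
    metadata: str
    traits: str
    outdir: str
    taxonomy: str | None = None
    min_reads: int = 5000
    min_otu_total: int = 10
    prevalence: float = 0.5
    r_threshold: float = 0.6
    q_threshold: float = 0.05
    rarefaction_depth: int = 5283
    rarefaction_reps: int = 1000
    permanova_perms: int = 999
    null_reps: int = 1000
    top_k_otus: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if self.min_reads < 0 or self.min_otu_total < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.rarefaction_depth <= 0 or self.rarefaction_reps < 1:
            raise ValueError("invalid rarefaction settings")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def stage_seed(self, stage: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))


(_S_ALPHA, _S_RAREFY_NET, _S_PERMANOVA, _S_NULL) = range(4)


@dataclass
class ReportBundle:
    config: dict
    versions: dict
    discarded_samples: list[str]
    responses: pd.DataFrame
    response_tests: dict
    anova: dict
    alpha: pd.DataFrame
    permanova_table: pd.DataFrame | None
    within_among: dict | None
    properties: dict[str, dict]
    null_comparison: dict[str, pd.DataFrame]
    link_regressions: pd.DataFrame
    abundance_screen: pd.DataFrame
    warnings_: list[str] = field(default_factory=list)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.responses.to_csv(out / "responses.csv", index=False, float_format=fmt)
        self.alpha.to_csv(out / "alpha_diversity.csv", float_format=fmt)
        if self.permanova_table is not None:
            self.permanova_table.to_csv(out / "permanova.csv", float_format=fmt)
        self.link_regressions.to_csv(out / "link_regressions.csv", index=False, float_format=fmt)
        self.abundance_screen.to_csv(out / "abundance_screen.csv", index=False, float_format=fmt)
        for inoc, table in self.null_comparison.items():
            table.to_csv(out / f"null_comparison_{inoc}.csv", float_format=fmt)
        payload = {
            "config": self.config,
            "versions": self.versions,
            "discarded_samples": self.discarded_samples,
            "response_tests": self.response_tests,
            "anova": self.anova,
            "within_among": self.within_among,
            "properties": self.properties,
            "warnings": self.warnings_,
        }
        (out / "report.json").write_text(_json_dumps(payload))
        (out / "report.txt").write_text(render_report(self))

    def hash(self) -> str:
        digest = hashlib.sha256()
        settings = {
            k: v
            for k, v in self.config.items()
            if k not in ("otu", "metadata", "taxonomy", "traits", "outdir")
        }
        digest.update(_json_dumps(settings).encode())
        digest.update(self.responses.round(10).to_csv(index=False).encode())
        digest.update(self.alpha.round(10).to_csv().encode())
        if self.permanova_table is not None:
            digest.update(self.permanova_table.round(10).to_csv().encode())
        digest.update(_json_dumps(self.properties).encode())
        digest.update(self.link_regressions.round(10).to_csv(index=False).encode())
        return digest.hexdigest()


def _json_dumps(obj) -> str:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    def clean(x):
        if isinstance(x, float):
            return round(x, 10) if np.isfinite(x) else None
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, list):
            return [clean(v) for v in x]
        return x

    return json.dumps(clean(json.loads(json.dumps(obj, default=default))),
                      indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig, tables=None) -> ReportBundle:
    """Run every stage; ``tables`` may inject (OtuTable, traits) directly."""
    warn_list: list[str] = []

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("read"):
        if tables is not None:
            table, traits = tables
        else:
            table = read_otu_table(config.otu, config.metadata, config.taxonomy)
            traits = read_traits(config.traits)

    with stage("filters"):
        from .io_tables import filter_low_depth_samples, filter_rare_otus

        table, discarded = filter_low_depth_samples(table, config.min_reads)
        table = filter_rare_otus(table, config.min_otu_total)

    with stage("responses"):
        responses = compute_responses(traits)
        response_tests = {
            "MGR": test_nonzero(responses["MGR"]),
            "PSF": test_nonzero(responses["PSF"]),
        }
        anova = {}
        for fieldname in ("total_biomass",):
            tab = two_way_anova(traits, fieldname)
            anova[fieldname] = {
                term: {"F": _nan_none(tab.loc[term, "F"]), "p": _nan_none(tab.loc[term, "p"])}
                for term in tab.index
                if term != "Residual"
            }

    with stage("diversity"):
        alpha = alpha_over_rarefactions(
            table,
            depth=config.rarefaction_depth,
            reps=config.rarefaction_reps,
            seed=np.random.default_rng(config.stage_seed(_S_ALPHA)),
        )
        root_ids = table.sample_meta.index[table.sample_meta["compartment"] == "root"]
        root = table.subset_samples(list(root_ids)) if len(root_ids) else table
        rarefied = rarefy_once(
            root,
            config.rarefaction_depth,
            np.random.default_rng(config.stage_seed(_S_RAREFY_NET)),
        )
        dist = bray_curtis(rarefied)
        perm_table = None
        wa = None
        if root.sample_meta["inoculum"].nunique() > 1:
            factors = root.sample_meta[["host", "inoculum"]]
            terms = ["host", "inoculum"]
            if root.sample_meta["host"].nunique() > 1:
                terms.append("host:inoculum")
            else:
                terms = ["inoculum"]
            perm_table = permanova(
                dist,
                factors,
                terms=terms,
                n_perm=config.permanova_perms,
                seed=np.random.default_rng(config.stage_seed(_S_PERMANOVA)),
            )
            wa = within_among_test(dist, root.sample_meta["inoculum"])

    with stage("networks"):
        nets = build_networks_by_group(
            rarefied,
            group_col="inoculum",
            min_fraction=config.prevalence,
            r_threshold=config.r_threshold,
            q_threshold=config.q_threshold,
        )
        properties = {}
        for inoc, net in nets.items():
            if net.graph.number_of_nodes() == 0:
                warn_list.append(f"network {inoc}: no OTUs after filtering")
                continue
            properties[inoc] = network_properties(net).as_dict()

    with stage("nulls"):
        null_comparison = {}
        null_rng = np.random.default_rng(config.stage_seed(_S_NULL))
        for inoc in sorted(properties):
            n = int(properties[inoc]["node"])
            m = int(properties[inoc]["edge"])
            if m == 0:
                warn_list.append(f"network {inoc}: empty edge set, null skipped")
                continue
            null = er_null_ensemble(n, m, reps=config.null_reps, seed=null_rng)
            obs = network_properties(nets[inoc])
            null_comparison[inoc] = compare_to_null(obs, null)

    with stage("linkage"):
        link_results = pd.DataFrame(
            columns=["predictor", "response", "slope", "intercept", "r2", "p", "n"]
        )
        nonempty = {i: nt for i, nt in nets.items() if nt.graph.number_of_edges() > 0}
        if not nonempty:
            warn_list.append("all networks empty: linkage skipped")
            records = pd.DataFrame()
        else:
            records = subnetwork_property_table(nets, rarefied, responses)
            fits = []
            for predictor in ("node", "edge", "average_degree"):
                for response in ("MGR", "PSF"):
                    if response in records.columns and np.ptp(records[predictor]) > 0:
                        fits.append(
                            link_regression(records, predictor, response).as_dict()
                        )
            if fits:
                link_results = pd.DataFrame(fits)
        screen = abundance_response_screen(
            rarefied, responses, top_k=min(config.top_k_otus, len(rarefied.otu_ids))
        )

    return ReportBundle(
        config=config.to_dict(),
        versions=_versions(),
        discarded_samples=discarded,
        responses=responses,
        response_tests=response_tests,
        anova=anova,
        alpha=alpha,
        permanova_table=perm_table,
        within_among=wa,
        properties=properties,
        null_comparison=null_comparison,
        link_regressions=link_results,
        abundance_screen=screen,
        warnings_=warn_list,
    )


def _nan_none(x):
    x = float(x)
    return None if not np.isfinite(x) else x


def _versions() -> dict:
    import networkx
    import scipy

    return {
        "mycolink": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }


def render_report(bundle: ReportBundle) -> str:
    """Human-readable summary with a Table-3-shaped property panel."""
    lines = ["mycolink pipeline report", "=" * 24, ""]
    lines.append(f"discarded low-depth samples: {bundle.discarded_samples or 'none'}")
    lines.append("")
    lines.append("Network properties")
    header = ["Network"] + [disp for _, disp in PANEL_DISPLAY]
    lines.append("\t".join(header))
    for inoc in sorted(bundle.properties):
        panel = bundle.properties[inoc]
        cells = [inoc]
        for key, _ in PANEL_DISPLAY:
            v = panel.get(key, float("nan"))
            if key in ("node", "edge"):
                cells.append(str(int(v)))
            elif key == "proportion_positive":
                cells.append("nan" if not np.isfinite(v) else f"{100 * v:.2f}%")
            else:
                cells.append("nan" if not np.isfinite(v) else f"{v:.3f}")
        lines.append("\t".join(cells))
    if not bundle.properties:
        lines.append("(no non-empty networks)")
    lines.append("")
    lines.append("Response vs network-complexity regressions")
    if len(bundle.link_regressions):
        lines.append(
            bundle.link_regressions.to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            )
        )
    else:
        lines.append("(skipped)")
    if bundle.warnings_:
        lines.append("")
        lines.append("Warnings:")
        lines.extend(f"- {w}" for w in bundle.warnings_)
    lines.append("")
    return "\n".join(lines)
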