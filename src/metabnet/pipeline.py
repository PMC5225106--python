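"""End-to-end workflow: normalize -> PCA -> PLS-DA -> differential tables
-> per-group networks -> intersections/SDNs -> HCA, with a manifest.

Configuration is a YAML file (or RunConfig object); every artifact is
written under the output directory and listed with a SHA-256 checksum
in ``manifest.json``, so a rerun with identical inputs and seed can be
verified byte for byte.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import hca as hca_mod
from . import io, multivariate, network, univariate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    peaks: str
    metadata: str
    out_dir: str
    internal_standard: str = "ribitol"
    r_min: float = 0.9
    q_max: float = 0.05
    vip_min: float = 1.0
    p_max: float = 0.05
    pca_components: int = 5
    plsda_folds: int = 7
    plsda_permutations: int = 100
    seed: int = 0
    compare: str = "genotype"
    within: tuple[str, ...] = ("condition", "timepoint")
    log2: bool = False
    standard_density: bool = False
    timepoint: str | None = None
    control_label: str = "CK"

    def validate(self) -> None:
        if not 0.0 <= self.r_min < 1.0:
            raise ValueError(f"r_min must lie in [0, 1), got {self.r_min}")
        if not 0.0 < self.q_max <= 1.0:
            raise ValueError(f"q_max must lie in (0, 1], got {self.q_max}")
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError(f"p_max must lie in (0, 1], got {self.p_max}")
        if self.vip_min < 0:
            raise ValueError("vip_min must be non-negative")
        if self.plsda_folds < 2:
            raise ValueError("plsda_folds must be >= 2")
        for path_attr in ("peaks", "metadata"):
            if not Path(getattr(self, path_attr)).exists():
                raise FileNotFoundError(getattr(self, path_attr))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "within" in data and isinstance(data["within"], list):
            data["within"] = tuple(data["within"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["within"] = list(self.within)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the artifact manifest.

    Any stage failure aborts with an error naming the stage; the
    manifest records parameters, seeds, and a checksum per output file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage_log: list[dict] = []

    def _stage(name: str):
        class _Timer:
            def __enter__(self):
                self.start = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                elapsed = time.perf_counter() - self.start
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                stage_log.append({"stage": name, "seconds": round(elapsed, 3)})
                logger.info("stage %s: done in %.2fs", name, elapsed)

        return _Timer()

    with _stage("normalize"):
        peaks = io.read_peak_table(config.peaks, config.metadata,
                                   internal_standard_name=config.internal_standard)
        norm = io.normalize_internal_standard(peaks)
        norm = io.handle_missing(norm)
        io.write_table(norm.values, out / "normalized.tsv")
        artifacts.append(out / "normalized.tsv")

    with _stage("pca"):
        scaled = multivariate.uv_scale(norm, log2=config.log2)
        n_comp = min(config.pca_components, scaled.x.shape[0] - 1, scaled.x.shape[1])
        pca = multivariate.run_pca(scaled, n_comp)
        io.write_table(pca.scores, out / "pca_scores.tsv")
        io.write_table(pca.loadings, out / "pca_loadings.tsv")
        pd.Series(pca.explained_variance_ratio,
                  index=pca.scores.columns, name="explained_fraction"
                  ).to_csv(out / "pca_variance.tsv", sep="\t")
        artifacts += [out / "pca_scores.tsv", out / "pca_loadings.tsv",
                      out / "pca_variance.tsv"]

    with _stage("plsda"):
        plsda = multivariate.run_plsda(
            scaled, norm.metadata[config.compare],
            cv_folds=config.plsda_folds, n_perm=config.plsda_permutations,
            seed=config.seed,
        )
        io.write_table(plsda.scores, out / "plsda_scores.tsv")
        plsda.vip.to_csv(out / "plsda_vip.tsv", sep="\t")
        summary = {
            "n_components": plsda.n_components,
            "R2X_cum": float(plsda.r2x[-1]),
            "R2Y_cum": float(plsda.r2y[-1]),
            "Q2_cum": plsda.q2_cum,
            "permutation_p": plsda.permutation_p,
            "classes": plsda.class_levels,
        }
        (out / "plsda_summary.txt").write_text(
            "".join(f"{k}\t{v}\n" for k, v in summary.items())
        )
        artifacts += [out / "plsda_scores.tsv", out / "plsda_vip.tsv",
                      out / "plsda_summary.txt"]

    with _stage("diff"):
        diff = univariate.differential_table(
            norm, compare=config.compare, within=config.within, vip=plsda.vip,
        )
        diff.to_csv(out / "diff.tsv", sep="\t", index=False)
        artifacts.append(out / "diff.tsv")

    with _stage("networks"):
        meta = norm.metadata
        genotypes = list(pd.unique(meta["genotype"].astype(str)))
        conditions = list(pd.unique(meta["condition"].astype(str)))
        nets: dict[tuple[str, str], network.CorrelationNetwork] = {}
        prop_rows = []
        for geno, cond in itertools.product(genotypes, conditions):
            r, p, n = network.correlation_matrix(
                norm, group=(geno, cond), timepoint=config.timepoint
            )
            net = network.build_network(
                r, p, label=f"{geno}:{cond}",
                r_min=config.r_min, q_max=config.q_max, n_samples=n,
            )
            nets[(geno, cond)] = net
            path = out / f"network_{geno}_{cond}.tsv"
            network.write_edge_list(net, path)
            network.write_graphml(net, out / f"network_{geno}_{cond}.graphml")
            props = network.network_properties(net)
            prop_rows.append({
                "group": net.label, "nodes": props.n_nodes, "edges": props.n_edges,
                "average_degree": props.average_degree,
                "density": props.standard_density if config.standard_density
                else props.density,
            })
            artifacts += [path, out / f"network_{geno}_{cond}.graphml"]
        pd.DataFrame(prop_rows).to_csv(out / "network_properties.tsv",
                                       sep="\t", index=False)
        artifacts.append(out / "network_properties.tsv")

    with _stage("sdn"):
        if len(genotypes) >= 2:
            ga, gb = genotypes[0], genotypes[1]
            sdn_rows = []
            for cond in conditions:
                sdn = network.symmetric_difference(nets[(ga, cond)], nets[(gb, cond)])
                inter = network.intersect_networks(nets[(ga, cond)], nets[(gb, cond)])
                network.write_edge_list(sdn, out / f"sdn_{cond}.tsv")
                network.write_graphml(sdn, out / f"sdn_{cond}.graphml")
                network.write_edge_list(inter, out / f"intersection_{cond}.tsv")
                sdn_rows.append({"condition": cond, **sdn.summary()})
                artifacts += [out / f"sdn_{cond}.tsv", out / f"sdn_{cond}.graphml",
                              out / f"intersection_{cond}.tsv"]
            pd.DataFrame(sdn_rows).to_csv(out / "sdn_summary.tsv", sep="\t", index=False)
            artifacts.append(out / "sdn_summary.tsv")

    with _stage("hca"):
        centered = hca_mod.center_by_control(
            norm, control_label=config.control_label, log2=config.log2
        )
        tree = hca_mod.cluster(centered)
        artifacts += hca_mod.write_hca(tree, out / "hca_")

    manifest = {
        "config": {**asdict(config), "within": list(config.within)},
        "stages": stage_log,
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in artifacts
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
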