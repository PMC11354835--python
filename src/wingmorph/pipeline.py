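"""End-to-end analysis pipeline.

Chains the stages of the identification workflow: read landmarks and
metadata -> GPA superimposition and tangent projection -> exploratory PCA
-> CVA per grouping (all apiaries, altitudinal floors, subspecies
references) -> discriminant classification of study specimens against the
pure references -> frequency tables -> Mahalanobis distance matrix over
all groups -> UPGMA dendrogram.  Every output CSV carries the run's config
hash and seed as a leading comment line; stage failures are re-raised with
the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import classify as _classify
from .cluster import upgma
from .errors import ConfigError, StageError
from .gpa import GeneralizedProcrustes, GPAResults
from .ordination import (
    CanonicalVariates,
    pca,
    size_covariate_correlation,
)
from .tps import Dataset, attach_metadata, read_tps

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    tps_path: Optional[str] = None
    metadata_path: Optional[str] = None
    dataset: Optional[Dataset] = None   # in-memory alternative to paths
    group_by: str = "apiary"            # grouping for the exploratory CVA
    var_retain: float = 0.99
    n_perm: int = 0                     # pairwise permutation tests (0 = skip)
    seed: int = 0
    priors: str = "equal"
    scale_policy: str = "apply"
    hybrid_reference: bool = False  # train an extra "AB" class from study wings
    africanized_classes: tuple[str, ...] = ("A. m. scutellata", "AB")
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if self.dataset is None:
            if self.tps_path is None:
                raise ConfigError("either dataset or tps_path is required")
            if not os.path.exists(self.tps_path):
                raise ConfigError(f"TPS file not found: {self.tps_path!r}")
            if self.metadata_path is not None and not os.path.exists(self.metadata_path):
                raise ConfigError(f"metadata file not found: {self.metadata_path!r}")

    def config_hash(self) -> str:
        # hash only the analysis-relevant settings, not output locations
        payload = {
            k: v for k, v in self.__dict__.items()
            if k not in ("dataset", "out_dir") and v is not None
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineReport:
    """Bundle of all pipeline outputs."""

    config: RunConfig
    gpa: GPAResults
    pca_result: object
    cva_groups: object                    # CVA over the chosen grouping
    cva_floors: Optional[object]          # CVA over altitudinal floors
    cva_all: object                       # CVA over apiaries+references+placebo
    correlation: Optional[object]
    lda: Optional[object]
    classification: Optional[object]
    confusion_frequency: Optional[pd.DataFrame]   # reference rows + query row, %
    floor_table: Optional[pd.DataFrame]           # Africanized/European x floors
    tree: object
    newick: str
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, out_dir: str) -> dict[str, str]:
        """Write CSV/Newick outputs; every CSV starts with a comment line
        carrying the config hash and seed (readable back with pandas'
        comment='#')."""
        os.makedirs(out_dir, exist_ok=True)
        header = f"# wingmorph config_hash={self.config.config_hash()} seed={self.config.seed}\n"
        paths: dict[str, str] = {}

        def write_csv(name: str, df: pd.DataFrame, index: bool = True) -> None:
            path = os.path.join(out_dir, name)
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(header)
                df.to_csv(fh, index=index, float_format="%.10g")
            paths[name] = path

        write_csv("aligned_tangent.csv", self.gpa.to_frame(), index=False)
        write_csv("mahalanobis_d.csv", self.cva_all.mahalanobis_d)
        write_csv("mahalanobis_d2.csv", self.cva_all.mahalanobis_d2)
        write_csv("cva_scores.csv", pd.DataFrame(
            self.cva_groups.scores,
            columns=[f"CV{i+1}" for i in range(self.cva_groups.scores.shape[1])],
        ).assign(group=self.cva_groups.score_labels.to_numpy()), index=False)
        if self.cva_all.perm_pvalues is not None:
            write_csv("perm_pvalues.csv", self.cva_all.perm_pvalues)
        if self.confusion_frequency is not None:
            write_csv("frequency_table.csv", self.confusion_frequency)
        if self.floor_table is not None:
            write_csv("floor_table.csv", self.floor_table)
        if self.lda is not None:
            write_csv("confusion_resub.csv", self.lda.confusion_resub)

        nwk_path = os.path.join(out_dir, "upgma.nwk")
        with open(nwk_path, "w", encoding="utf-8") as fh:
            fh.write(header)
            fh.write(self.newick + "\n")
        paths["upgma.nwk"] = nwk_path

        log_path = os.path.join(out_dir, "run_log.txt")
        with open(log_path, "w", encoding="utf-8") as fh:
            fh.write(header)
            fh.write(self.summary() + "\n")
            fh.write("\nstage timings (s):\n")
            for stage, dt in self.timings.items():
                fh.write(f"  {stage}: {dt:.2f}\n")
        paths["run_log.txt"] = log_path
        return paths

    def summary(self) -> str:
        lines = [
            "wingmorph pipeline report",
            "=" * 45,
            f"specimens: {self.gpa.n}   landmarks: {self.gpa.k}",
            f"GPA iterations: {self.gpa.n_iter}",
        ]
        if self.correlation is not None:
            lines.append(self.correlation.summary())
        lines.append(
            f"CVA ({self.config.group_by}): "
            f"{self.cva_groups.n_groups} groups, "
            f"{self.cva_groups.n_axes_for(0.80)} CVs for 80% of variation"
        )
        if self.lda is not None:
            lines.append(
                f"DFA resubstitution accuracy: {100 * self.lda.accuracy_resub:.2f}%"
            )
        if self.confusion_frequency is not None:
            lines += ["", "frequency table (%):", str(self.confusion_frequency.round(1))]
        if self.floor_table is not None:
            lines += ["", "morphotypes by altitudinal floor (%):",
                      str(self.floor_table.round(1))]
        lines += ["", f"UPGMA over {len(self.tree.leaf_names)} groups; "
                      f"tree height {self.tree.height:.4g}"]
        return "\n".join(lines)


def _stage(name: str, timings: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s ...", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = time.perf_counter() - self.t0
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run the full analysis; returns the report bundle (and writes files
    when config.out_dir is set)."""
    config.validate()
    timings: dict[str, float] = {}

    with _stage("read", timings):
        if config.dataset is not None:
            dataset = config.dataset
        else:
            dataset = read_tps(config.tps_path, scale_policy=config.scale_policy)
            if config.metadata_path is not None:
                dataset = attach_metadata(dataset, config.metadata_path)

    with _stage("gpa", timings):
        gpa_res = GeneralizedProcrustes(dataset).fit()
        meta = gpa_res.metadata

    with _stage("pca", timings):
        pca_res = pca(gpa_res.tangent)

    group_label = meta["group_label"] if meta is not None else pd.Series(
        [None] * gpa_res.n
    )
    is_reference = group_label.notna().to_numpy() & (
        group_label != "placebo"
    ).to_numpy()
    is_query = ~group_label.notna().to_numpy()

    with _stage("cva_groups", timings):
        if config.group_by == "apiary":
            labels = meta["apiary"]
        elif config.group_by == "floor":
            labels = meta["floor"]
        elif config.group_by == "subspecies":
            labels = group_label
        else:
            raise ConfigError(f"unknown group_by {config.group_by!r}")
        if labels.notna().sum() < 4:
            raise ConfigError(
                f"grouping {config.group_by!r} needs labelled specimens; "
                "is the metadata attached?"
            )
        cva_groups = CanonicalVariates(
            gpa_res.tangent, labels, var_retain=config.var_retain
        ).fit()

    cva_floors = None
    correlation = None
    if meta is not None and meta["altitude_masl"].notna().any():
        with _stage("floors", timings):
            floors = meta["floor"]
            if floors[is_query].notna().sum() >= 4 and floors[is_query].nunique() >= 2:
                q = is_query
                cva_floors = CanonicalVariates(
                    gpa_res.tangent[q], floors[q].reset_index(drop=True),
                    var_retain=config.var_retain,
                ).fit()
        with _stage("correlation", timings):
            alt = meta["altitude_masl"].to_numpy(dtype=float)
            ok = np.isfinite(alt) & is_query
            if ok.sum() >= 3:
                correlation = size_covariate_correlation(
                    gpa_res.centroid_sizes[ok], alt[ok]
                )

    lda_res = None
    classification = None
    confusion_frequency = None
    floor_table = None
    if is_reference.sum() >= 4 and pd.Series(group_label[is_reference]).nunique() >= 2:
        with _stage("classify", timings):
            ref_labels = group_label.where(
                pd.Series(is_reference, index=group_label.index), other=pd.NA
            )
            if config.hybrid_reference and is_query.any():
                # Africanized-hybrid mode: study wings form a fifth ("AB")
                # training class; classifying them is then resubstitution
                ref_labels = ref_labels.where(
                    ~pd.Series(is_query, index=ref_labels.index), other="AB"
                )
            lda_res = _classify.LinearDiscriminant(
                gpa_res.tangent, ref_labels, priors=config.priors,
                var_retain=config.var_retain, provenance=gpa_res.provenance,
            ).fit()
            if is_query.any():
                ids = [sid for sid, q in zip(gpa_res.ids, is_query) if q]
                classification = lda_res.classify(
                    gpa_res.tangent[is_query], ids=ids,
                    provenance=gpa_res.provenance,
                )
        with _stage("tables", timings):
            ref_names = lda_res.group_names
            freq_ref = (
                lda_res.confusion_resub
                .div(lda_res.confusion_resub.sum(axis=1), axis=0) * 100
            )
            # in hybrid mode the study wings appear as the AB training
            # class; they are re-added below as the AB* query row
            freq_ref = freq_ref.drop(index=["AB"], errors="ignore")
            rows = [freq_ref]
            if classification is not None:
                q_counts = classification.assigned.value_counts()
                q_freq = (
                    q_counts.reindex(ref_names, fill_value=0)
                    / q_counts.sum() * 100
                )
                rows.append(pd.DataFrame([q_freq], index=["AB*"]))
            confusion_frequency = pd.concat(rows).fillna(0.0)
            confusion_frequency.index.name = "known_group"
            if (
                classification is not None
                and meta is not None
                and meta.loc[is_query, "floor"].notna().all()
            ):
                floor_table = _classify.africanized_table(
                    classification.assigned.to_numpy(),
                    meta.loc[is_query, "floor"].to_numpy(),
                    africanized_classes=config.africanized_classes,
                )

    with _stage("cva_all", timings):
        all_labels = group_label.copy()
        if meta is not None:
            apiaries = meta["apiary"]
            all_labels = all_labels.where(all_labels.notna(), apiaries)
        cva_all = CanonicalVariates(
            gpa_res.tangent, all_labels, var_retain=config.var_retain
        ).fit()
        if config.n_perm > 0:
            cva_all.permutation_test(n_perm=config.n_perm, seed=config.seed)

    with _stage("upgma", timings):
        tree = upgma(cva_all.mahalanobis_d)
        newick = tree.to_newick()

    report = PipelineReport(
        config=config, gpa=gpa_res, pca_result=pca_res,
        cva_groups=cva_groups, cva_floors=cva_floors, cva_all=cva_all,
        correlation=correlation, lda=lda_res, classification=classification,
        confusion_frequency=confusion_frequency, floor_table=floor_table,
        tree=tree, newick=newick, timings=timings,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
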