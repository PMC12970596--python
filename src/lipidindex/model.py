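"""Model/Results surface for functional-index analysis.

:class:`FunctionalLipidModel` is built from an abundance matrix and a
sample-to-group map (``from_csv`` reads the standard input files).  Building
the model parses the lipid names and computes the samples x indices matrix;
``fit(exp, ctrl)`` runs the two-group comparison and returns a
:class:`FunctionalLipidResults` carrying the per-index statistics,
functional dominance, biomarker ranking, protein seeds and enzyme direction
calls, with a ``summary()`` table.  Multivariate views (PCA, PLS-DA,
clustered heatmap, correlations) hang off the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as _io
from . import multivariate as mv
from . import network as net
from . import stats as st
from .engine import IndexMatrix, compute_index_matrix
from .library import load_index_library
from .nomenclature import parse_profile

__version__ = "0.1.0"


class FunctionalLipidModel:
    """Functional-index model of a quantitative lipidomics study.

    Parameters
    ----------
    abundance : DataFrame
        Lipids x samples matrix of non-negative intensities/concentrations;
        row labels are shorthand lipid names.
    groups : Series
        Sample -> group label, covering every column of ``abundance``.
    library : sequence of IndexDefinition, optional
        Defaults to the packaged 42-index library.
    """

    def __init__(self, abundance: pd.DataFrame, groups: pd.Series, library=None):
        if abundance.shape[0] == 0 or abundance.shape[1] == 0:
            raise ValueError("empty abundance matrix")
        missing = [c for c in abundance.columns if c not in groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.library = tuple(library) if library is not None else load_index_library()
        report = parse_profile(abundance.index)
        self.records = report.records
        self.parse_skipped = report.skipped
        self.abundance = abundance.loc[[n for n in abundance.index if n in self.records]]
        self.groups = groups.loc[list(abundance.columns)].astype(str)
        self._index_matrix: Optional[IndexMatrix] = None

    @classmethod
    def from_csv(cls, matrix_path, groups_path, orientation="auto", library=None):
        study = _io.read_study(matrix_path, groups_path, orientation)
        return cls(study.abundance, study.groups, library=library)

    @property
    def index_matrix(self) -> IndexMatrix:
        if self._index_matrix is None:
            self._index_matrix = compute_index_matrix(
                self.abundance, self.library, self.records
            )
        return self._index_matrix

    @property
    def group_labels(self) -> list[str]:
        return list(pd.unique(self.groups))

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        group_exp: Optional[str] = None,
        group_ctrl: Optional[str] = None,
        p_threshold: float = 0.05,
        fc_threshold: float = 1.0,
        fdr: bool = False,
    ) -> "FunctionalLipidResults":
        """Two-group comparison of all indices (Welch test + delta-method SE).

        With more than two group labels and no explicit pair, use
        :meth:`fit_anova` instead.
        """
        labels = self.group_labels
        if group_exp is None or group_ctrl is None:
            if len(labels) != 2:
                raise ValueError(
                    f"{len(labels)} groups present; pass group_exp/group_ctrl "
                    "or use fit_anova()"
                )
            group_exp, group_ctrl = labels
        for g in (group_exp, group_ctrl):
            if (self.groups == g).sum() < 2:
                raise ValueError(f"group {g!r} needs at least 2 samples")
        table = st.compare_all_indices(
            self.index_matrix, self.groups, group_exp, group_ctrl,
            p_threshold=p_threshold, fc_threshold=fc_threshold, fdr=fdr,
        )
        return FunctionalLipidResults(
            model=self, comparison=table, group_exp=group_exp,
            group_ctrl=group_ctrl, p_threshold=p_threshold,
            fc_threshold=fc_threshold,
        )

    def fit_anova(self, labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Per-index one-way Welch ANOVA across >2 groups."""
        return st.anova_all_indices(self.index_matrix, self.groups, labels)

    # --------------------------------------------------------- multivariate
    def scaled(self, scaling: str = "autoscale") -> mv.ScaledMatrix:
        return mv.scale_matrix(self.index_matrix.values, method=scaling)

    def pca(self, n_components: Optional[int] = None, scaling: str = "autoscale"):
        return mv.pca(self.scaled(scaling), n_components)

    def plsda(self, n_components: int = 2, scaling: str = "autoscale"):
        return mv.plsda(self.scaled(scaling), self.groups, n_components)

    def heatmap(
        self,
        distance: str = "euclidean",
        linkage: str = "complete",
        top_n: Optional[int] = None,
        scaling: str = "autoscale",
    ):
        return mv.cluster_heatmap(
            self.index_matrix.values, distance, linkage, top_n, scaling
        )

    def correlations(self, method: str = "pearson") -> pd.DataFrame:
        return st.correlation_matrix(self.index_matrix, method)


@dataclass
class FunctionalLipidResults:
    """Results of a two-group functional-index comparison."""

    model: FunctionalLipidModel
    comparison: pd.DataFrame
    group_exp: str
    group_ctrl: str
    p_threshold: float
    fc_threshold: float
    _biomarkers: Optional[pd.DataFrame] = field(default=None, repr=False)

    # ------------------------------------------------------------- tables
    def dominance(self) -> pd.DataFrame:
        return st.functional_dominance(self.comparison)

    def biomarkers(self, top: int = 20) -> pd.DataFrame:
        return st.biomarker_rank(
            self.model.index_matrix, self.model.groups,
            self.group_exp, self.group_ctrl, alpha=self.p_threshold, top=top,
        )

    def volcano_table(self) -> pd.DataFrame:
        """Comparable rows split-ready by category (volcano plot backing)."""
        t = self.comparison
        cols = ["index_id", "name", "category", "log2fc", "se_log2fc",
                "p_value", "significant", "interpretation"]
        return t.loc[t["comparable"], cols].reset_index(drop=True)

    def significant(self) -> pd.DataFrame:
        return self.comparison[self.comparison["significant"]].reset_index(drop=True)

    def protein_seeds(self) -> dict[str, set]:
        return net.significant_index_proteins(self.comparison, self.model.library)

    def enzyme_calls(self, reactions=None, tolerance: float = 0.10):
        return net.enzyme_direction_call(
            self.model.abundance, self.model.records, self.model.groups,
            self.group_exp, self.group_ctrl, reactions=reactions,
            comparison_table=self.comparison, library=self.model.library,
            tolerance=tolerance,
        )

    def string_request(self, **params) -> dict:
        proteins = sorted(self.protein_seeds())
        return net.build_string_request(proteins, **params)

    # ------------------------------------------------------------ summary
    def summary(self) -> str:
        t = self.comparison
        n_eval = int(t["comparable"].sum()) if not t.empty else 0
        n_sig = int(t["significant"].sum()) if not t.empty else 0
        lines = [
            "Functional lipid index comparison",
            "=" * 70,
            f"groups: {self.group_exp} (n={int((self.model.groups == self.group_exp).sum())})"
            f" vs {self.group_ctrl} (n={int((self.model.groups == self.group_ctrl).sum())})",
            f"indices evaluated: {n_eval} / {len(self.model.library)}"
            f"   significant (p<{self.p_threshold:g}, |log2FC|>={self.fc_threshold:g}): {n_sig}",
            "",
        ]
        dom = self.dominance()
        lines.append("functional dominance (sum |log2FC| of significant / n evaluated):")
        for _, row in dom.iterrows():
            d = "NA" if pd.isna(row["dominance"]) else f"{row['dominance']:.4f}"
            lines.append(
                f"  {row['category']:<12} {d:>8}   "
                f"({row['n_significant']}/{row['n_evaluated']} significant)"
            )
        if n_sig:
            lines.append("")
            lines.append(
                f"{'index':<28}{'log2FC':>8}{'SE':>8}{'p':>12}{'AUC':>7}{'d':>8}"
            )
            lines.append("-" * 70)
            sig = t[t["significant"]].sort_values("p_value")
            for _, r in sig.iterrows():
                lines.append(
                    f"{r['name'][:27]:<28}{r['log2fc']:>8.3f}{r['se_log2fc']:>8.3f}"
                    f"{r['p_value']:>12.3e}{r['auc']:>7.3f}{r['cohens_d']:>8.2f}"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------- export
    def to_csv(self, outdir) -> dict[str, Path]:
        outdir = _io.ensure_dir(outdir)
        paths = {}
        paths["functional_summary"] = outdir / "functional_summary.csv"
        _io.write_table(self.comparison, paths["functional_summary"])
        paths["volcano_table"] = outdir / "volcano_table.csv"
        _io.write_table(self.volcano_table(), paths["volcano_table"])
        paths["dominance"] = outdir / "dominance.csv"
        _io.write_table(self.dominance(), paths["dominance"])
        paths["biomarker_top20"] = outdir / "biomarker_top20.csv"
        _io.write_table(self.biomarkers(), paths["biomarker_top20"])
        return paths


def run_pipeline(
    abundance: pd.DataFrame,
    groups: pd.Series,
    outdir,
    group_exp: Optional[str] = None,
    group_ctrl: Optional[str] = None,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    scaling: str = "autoscale",
    distance: str = "euclidean",
    heatmap_linkage: str = "complete",
    top_n: Optional[int] = None,
    correlation_method: str = "pearson",
    seed: Optional[int] = None,
    plots: bool = True,
    string_params: Optional[dict] = None,
) -> dict:
    """Run the full workflow and write a deterministic result bundle.

    Writes index_matrix.csv, functional_summary.csv, volcano_table.csv,
    dominance.csv, biomarker_top20.csv, correlations.csv, the multivariate
    outputs (scores/loadings/explained/vip/heatmap matrices + merge tables),
    enzyme_calls.csv, string_request.json and a run log.  With >2 groups
    the comparison switches to the per-index Welch ANOVA table
    (anova_table.csv) and the two-group-only outputs are skipped.
    """
    outdir = _io.ensure_dir(outdir)
    model = FunctionalLipidModel(abundance, groups)
    im = model.index_matrix
    im.to_csv(outdir / "index_matrix.csv")

    labels = model.group_labels
    results = None
    if len(labels) == 2 or (group_exp and group_ctrl):
        results = model.fit(group_exp, group_ctrl, p_threshold, fc_threshold)
        results.to_csv(outdir)
        calls = results.enzyme_calls()
        _io.write_table(net.enzyme_calls_frame(calls), outdir / "enzyme_calls.csv")
        seeds = results.protein_seeds()
        if seeds:
            payload = results.string_request(**(string_params or {}))
        else:
            payload = {"note": "no significant indices; no proteins to query"}
        net.write_string_request(payload, outdir / "string_request.json")
    else:
        _io.write_table(model.fit_anova(), outdir / "anova_table.csv")

    corr = model.correlations(correlation_method)
    corr.to_csv(outdir / "correlations.csv", na_rep=_io.NA_REP, float_format=_io.FLOAT_FORMAT)

    pca_model = model.pca(scaling=scaling)
    pca_model.scores.to_csv(outdir / "scores.csv", float_format=_io.FLOAT_FORMAT, index_label="sample")
    pca_model.loadings.to_csv(outdir / "loadings.csv", float_format=_io.FLOAT_FORMAT, index_label="index")
    pd.DataFrame(
        {"component": pca_model.scores.columns, "explained_fraction": pca_model.explained}
    ).to_csv(outdir / "explained.csv", index=False, float_format=_io.FLOAT_FORMAT)

    pls = model.plsda(scaling=scaling)
    pls.scores.to_csv(outdir / "plsda_scores.csv", float_format=_io.FLOAT_FORMAT, index_label="sample")
    pls.loadings.to_csv(outdir / "plsda_loadings.csv", float_format=_io.FLOAT_FORMAT, index_label="index")
    pls.vip.rename_axis("index").to_csv(outdir / "vip.csv", float_format=_io.FLOAT_FORMAT)

    hm = model.heatmap(distance, heatmap_linkage, top_n, scaling)
    hm.matrix.to_csv(outdir / "heatmap_matrix.csv", float_format=_io.FLOAT_FORMAT, index_label="sample")
    pd.DataFrame(hm.sample_linkage, columns=["left", "right", "height", "count"]).to_csv(
        outdir / "heatmap_sample_merges.csv", index=False, float_format="%.10g"
    )
    pd.DataFrame(hm.index_linkage, columns=["left", "right", "height", "count"]).to_csv(
        outdir / "heatmap_index_merges.csv", index=False, float_format="%.10g"
    )

    if plots:
        from . import plots as pl

        pl.emit_all(model, results, pca_model, pls, hm, corr, outdir)

    _io.write_run_log(
        outdir / "run_log.json",
        version=__version__,
        seed=seed,
        groups={g: int((groups == g).sum()) for g in labels},
        p_threshold=p_threshold,
        fc_threshold=fc_threshold,
        scaling=scaling,
        distance=distance,
        n_lipids=int(model.abundance.shape[0]),
        n_skipped=len(model.parse_skipped),
        indices_not_evaluated=im.not_evaluated,
    )
    return {"model": model, "results": results, "outdir": outdir}
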