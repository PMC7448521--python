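"""Model/Results interface over the scan machinery.

:class:`ProteinScanModel` holds a gene's variants, score statistics and 3D
coordinates; :meth:`fit` runs the window enumeration and set-based tests
and returns :class:`ScanResults` with the gene-level p-value, the
per-window table and a ``summary()``.  Signal-region detection hangs off
the results object and reuses the Monte-Carlo null of the fit when one was
computed.  :class:`Scan1DModel` is the chromosome-position comparator; it
differs only in how the window set is built.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import combine, signal
from .combine import CAUCHY, MINP, GeneResult, WindowEngine, mc_null_min_p
from .data import (
    IndividualData,
    SpatialMap,
    SummaryStats,
    VariantTable,
    compute_score_stats,
    variant_table_from_genotypes,
)
from .scan1d import Scan1DConfig, make_1d_windows
from .setbased import MEAN
from .signal import SignalReport, significance_threshold
from .windows import WindowSet, build_window_set

__all__ = ["ProteinScanModel", "Scan1DModel", "ScanResults"]


class _BaseScanModel:
    """Shared fitting logic; subclasses provide the window set."""

    def __init__(self, variants: VariantTable, stats: SummaryStats, gene_id: str = "gene"):
        if stats.m != len(variants):
            raise ValueError("summary statistics and variant table sizes differ")
        self.variants = variants
        self.stats = stats
        self.gene_id = gene_id

    def _window_set(self, min_mac: int) -> WindowSet:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(
        self,
        test: str = MEAN,
        combine_method: str = CAUCHY,
        weights: str | None = None,
        min_mac: int = 10,
        B: int = 5000,
        seed=None,
    ) -> "ScanResults":
        """Run the scan test.

        Parameters
        ----------
        test : "mean" or "variance"
        combine_method : "cauchy" (analytic, genome-wide) or "minp"
            (Monte-Carlo null, candidate-gene)
        weights : weight scheme; defaults to Madsen-Browning for the mean
            test and the Beta(1,25) density for the variance test
        min_mac : windows with cumulative minor allele count below this are
            not tested
        B, seed : Monte-Carlo replicates and seed for the "minp" null
        """
        ws = self._window_set(min_mac)
        res = combine.gene_pvalue(
            self.stats,
            ws,
            self.variants,
            test_kind=test,
            weights=weights,
            method=combine_method,
            B=B,
            seed=seed,
            gene_id=self.gene_id,
        )
        return ScanResults(self, ws, res, test, weights, B=B, seed=seed)


class ProteinScanModel(_BaseScanModel):
    """Gene-level association scan over flexibly shaped 3D windows.

    Parameters
    ----------
    variants : VariantTable
    stats : SummaryStats
        Score vector U and covariance V aligned to ``variants``.
    spatial : SpatialMap, optional
        Variant coordinates; if omitted every variant is unmapped and the
        model reduces to a single whole-gene test.
    """

    def __init__(
        self,
        variants: VariantTable,
        stats: SummaryStats,
        spatial: SpatialMap | None = None,
        gene_id: str = "gene",
    ):
        super().__init__(variants, stats, gene_id)
        self.spatial = spatial if spatial is not None else SpatialMap.all_unmapped(len(variants))
        if len(self.spatial) != len(variants):
            raise ValueError("spatial map and variant table sizes differ")

    @classmethod
    def from_individual_data(
        cls,
        data: IndividualData,
        spatial: SpatialMap | None = None,
        variants: VariantTable | None = None,
        gene_id: str = "gene",
    ) -> "ProteinScanModel":
        """Build the model from genotypes/phenotype/covariates, computing
        the score statistics under the linear null model.  MAF and MAC are
        recomputed from the genotype matrix."""
        stats = compute_score_stats(data)
        if variants is None:
            variants = variant_table_from_genotypes(data.G)
        else:
            recomputed = variant_table_from_genotypes(
                data.G, variant_id=variants.variant_id,
                pos=variants.pos,
            )
            recomputed.chrom = variants.chrom
            variants = recomputed
        return cls(variants, stats, spatial, gene_id=gene_id)

    def _window_set(self, min_mac: int) -> WindowSet:
        return build_window_set(self.spatial, self.variants, min_mac=min_mac)


class Scan1DModel(_BaseScanModel):
    """Comparator scan over fixed-size chromosomal windows."""

    def __init__(
        self,
        variants: VariantTable,
        stats: SummaryStats,
        config: Scan1DConfig | None = None,
        gene_id: str = "gene",
    ):
        super().__init__(variants, stats, gene_id)
        self.config = config or Scan1DConfig()

    def _window_set(self, min_mac: int) -> WindowSet:
        return make_1d_windows(
            self.variants.pos, self.config, variants=self.variants, min_mac=min_mac
        )


class ScanResults:
    """Fitted scan-test results.

    Attributes
    ----------
    gene_pvalue : float
    gene_result : GeneResult
    window_set : WindowSet
    """

    def __init__(self, model, ws: WindowSet, res: GeneResult, test: str, weights, B: int, seed):
        self.model = model
        self.window_set = ws
        self.gene_result = res
        self.test = test
        self.weights = weights
        self.B = B
        self.seed = seed

    @property
    def gene_pvalue(self) -> float:
        return self.gene_result.p

    @property
    def n_windows_tested(self) -> int:
        return self.gene_result.n_windows_tested

    def window_table(self) -> pd.DataFrame:
        variants = self.model.variants
        rows = []
        for w, p in self.gene_result.window_results:
            ids = ",".join(str(variants.variant_id[j]) for j in w.sorted_members())
            rows.append((w.provenance, w.size, w.mac, p, ids))
        return (
            pd.DataFrame(rows, columns=["provenance", "size", "mac", "p", "members"])
            .sort_values("p", kind="stable")
            .reset_index(drop=True)
        )

    def detect_signals(
        self, alpha: float = 0.05, overlap_fraction: float | None = None,
        B: int | None = None, seed=None,
    ) -> SignalReport:
        """Signal-region detection at family-wise level ``alpha``.

        Reuses the Monte-Carlo null from a "minp" fit when available,
        otherwise draws a fresh one (B defaults to the fit's B).
        """
        res = self.gene_result
        if res.null_min_p is not None and (B is None or B == res.mc_reps_used) and seed is None:
            null = res.null_min_p
        else:
            null = mc_null_min_p(
                self.model.stats,
                self.window_set,
                test_kind=self.test,
                weights=self.weights,
                B=B or self.B,
                seed=seed if seed is not None else self.seed,
                variants=self.model.variants,
            )
        thr = significance_threshold(null, alpha)
        # threshold comparison uses the same evaluator as the null sample
        engine = WindowEngine(
            self.model.stats, self.window_set, self.model.variants, self.test, self.weights
        )
        batch_p = engine.pvalues_batch(self.model.stats.U[:, None]).ravel()
        results = list(zip(engine.windows, batch_p))
        if overlap_fraction is None:
            return signal.detect_signal_regions(results, thr, alpha=alpha)
        return signal.detect_signal_regions_overlap(results, thr, overlap_fraction, alpha=alpha)

    def summary(self) -> str:
        res = self.gene_result
        lines = [
            "Scan test results",
            "=" * 46,
            f"gene:             {res.gene_id}",
            f"model:            {type(self.model).__name__}",
            f"test:             {self.test}",
            f"combination:      {res.method}",
            f"windows tested:   {res.n_windows_tested}",
            f"gene p-value:     {res.p:.4g}",
        ]
        if res.mc_reps_used:
            lines.append(f"MC replicates:    {res.mc_reps_used}")
        tbl = self.window_table().head(10)
        lines += ["", "top windows (by p):", tbl.to_string(index=False)]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ScanResults gene={self.gene_result.gene_id!r} test={self.test} "
            f"p={self.gene_result.p:.3g} windows={self.n_windows_tested}>"
        )
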