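"""Model/Results front-end for the splice-site comparison pipeline.

`SpliceSiteComparison` bundles a dataset, a partition criterion and a
recognition-loop model; `.fit()` runs the full resampling analysis (sKL
divergence with resampling control, bootstrap difference tests, optional
nucleotide-level bootstrap, Dunn correction plan) and returns a
`SpliceSiteComparisonResults` carrying the estimates, their resampling
uncertainty, and a `summary()` table.  `PsiGroupComparison` does the same
for the +1G-mutation PSI re-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as sps
from .dataset import SpliceDataset, classify_dataset, partition_dataset
from .pairing import LoopModel, default_loop_model
from .psi import MutationRecord, group_compare
from .stats import (BootstrapResult, CorrectionPlan, NucleotideBootstrapResult,
                    PairClassDistribution, SKLResult, SubsiteSpec)

__all__ = ["SpliceSiteComparison", "SpliceSiteComparisonResults",
           "PsiGroupComparison"]

#: loop model conventionally paired with each partition criterion
_CRITERION_MODEL = {"plus5G": "U5_loop1", "minus1G": "U6_acagaga",
                    "minus3C": "U5_loop1"}


class SpliceSiteComparison:
    """Compare base-pair class frequencies between conserved/substituted groups.

    Parameters
    ----------
    dataset
        A classified :class:`SpliceDataset` (classification is applied if
        missing).
    criterion
        ``"plus5G"``, ``"minus1G"`` or ``"minus3C"`` — the conserved
        position defining the two groups.
    loop_model
        Recognition element whose base pairs are scored; defaults to the
        element the criterion interrogates (U5 Loop1 for the exon-junction
        experiments, the U6 box for ``minus1G``).
    subsites
        Position groups for the sKL analysis; defaults to the published
        groupings for the loop.
    """

    def __init__(self, dataset: SpliceDataset, criterion: str = "plus5G",
                 loop_model: LoopModel | None = None,
                 subsites: list[SubsiteSpec] | None = None):
        if any(not r.spliceosome_class for r in dataset.records):
            classify_dataset(dataset)
        self.dataset = dataset
        self.criterion = criterion
        self.loop_model = loop_model or default_loop_model(_CRITERION_MODEL[criterion])
        self.subsites = subsites or sps.default_subsites(self.loop_model.name)
        conserved, substituted = partition_dataset(dataset, criterion)
        self.conserved = sps.class_matrix(conserved, self.loop_model)
        self.substituted = sps.class_matrix(substituted, self.loop_model)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "SpliceSiteComparison":
        return cls(SpliceDataset.from_tsv(path), **kwargs)

    def fit(self, iterations: int = 10_000, seed: int | None = None,
            run_skl: bool = True, run_bootstrap: bool = True,
            nucleotide_position: str | None = None,
            extra_tests: list[tuple[int, float]] | None = None,
            ) -> "SpliceSiteComparisonResults":
        """Run the resampling analyses and return a results object.

        Subsidiary seeds for the sKL, bootstrap and nucleotide stages are
        derived from ``seed`` by fixed offsets so each stage is
        independently reproducible.
        """
        seeds = (None, None, None) if seed is None else (seed, seed + 1, seed + 2)
        skl = None
        if run_skl:
            skl = sps.skl_control_experiment(
                self.conserved, self.substituted, subsites=self.subsites,
                iterations=iterations, seed=seeds[0])
        boot = None
        if run_bootstrap:
            boot = sps.bootstrap_differences(
                self.substituted, self.conserved,
                iterations=iterations, seed=seeds[1])
        nuc = None
        if nucleotide_position is not None:
            nuc = sps.nucleotide_bootstrap(
                nucleotide_position, self.substituted, self.conserved,
                iterations=iterations, seed=seeds[2])
            extra_tests = list(extra_tests or []) + [(4, 0.33)]
        plan = sps.build_correction_plan(self.loop_model, extra_tests=extra_tests)
        return SpliceSiteComparisonResults(
            model=self,
            freq_conserved=sps.position_frequencies(self.conserved),
            freq_substituted=sps.position_frequencies(self.substituted),
            skl=skl, bootstrap=boot, nucleotide=nuc, correction=plan,
            iterations=iterations, seed=seed,
        )


@dataclass
class SpliceSiteComparisonResults:
    """Estimates and resampling uncertainty from a fitted comparison."""

    model: SpliceSiteComparison
    freq_conserved: PairClassDistribution
    freq_substituted: PairClassDistribution
    skl: dict[str, SKLResult] | None
    bootstrap: BootstrapResult | None
    nucleotide: NucleotideBootstrapResult | None
    correction: CorrectionPlan
    iterations: int
    seed: int | None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.provenance.setdefault("criterion", self.model.criterion)
        self.provenance.setdefault("loop_model", self.model.loop_model.name)
        self.provenance.setdefault("n_conserved", self.model.conserved.n)
        self.provenance.setdefault("n_substituted", self.model.substituted.n)
        self.provenance.setdefault("iterations", self.iterations)
        self.provenance.setdefault("seed", self.seed)

    # -- tables -------------------------------------------------------------

    def skl_table(self) -> pd.DataFrame | None:
        if self.skl is None:
            return None
        return pd.DataFrame([
            {"subsite": name, "mean_case_skl": r.case_values.mean(),
             "mean_control_skl": r.control_values.mean(),
             "mean_ratio_phi": r.mean_ratio}
            for name, r in self.skl.items()])

    def significance_table(self) -> pd.DataFrame | None:
        """P(H0) per cell with plain and correlation-adjusted Dunn flags."""
        if self.bootstrap is None:
            return None
        df = self.bootstrap.to_frame()
        df["significant_plain"] = df["p_h0"] < self.correction.alpha_prime
        df["significant_adjusted"] = df["p_h0"] < self.correction.alpha_prime_adjusted
        return df

    def summary(self) -> str:
        m = self.model
        lines = [
            "Splice-site base-pair comparison",
            "=" * 48,
            f"criterion:      {m.criterion}",
            f"loop model:     {m.loop_model.name}",
            f"groups:         conserved n={m.conserved.n}, "
            f"substituted n={m.substituted.n}",
            f"iterations:     {self.iterations}   seed: {self.seed}",
            f"tests:          m={self.correction.m} (alpha'={self.correction.alpha_prime}), "
            f"m'={self.correction.m_prime} "
            f"(alpha'={self.correction.alpha_prime_adjusted})",
        ]
        skl = self.skl_table()
        if skl is not None:
            lines += ["", "sKL divergence by subsite (phi = mean case / mean control)",
                      skl.to_string(index=False, float_format=lambda x: f"{x:.4g}")]
        sig = self.significance_table()
        if sig is not None:
            show = sig[sig["significant_adjusted"]]
            lines += ["", f"bootstrap cells significant at alpha' = "
                          f"{self.correction.alpha_prime_adjusted} "
                          f"({len(show)} of {len(sig)}):"]
            if len(show):
                lines.append(show.to_string(
                    index=False, float_format=lambda x: f"{x:.4g}"))
        if self.nucleotide is not None:
            lines += ["", f"nucleotide bootstrap at {self.nucleotide.position}: "
                          f"P(H0) = " + ", ".join(
                              f"{k}:{v:.4g}" for k, v in self.nucleotide.p_h0.items())]
        return "\n".join(lines)


class PsiGroupComparison:
    """PSI comparison of +1G-mutant exons with and without +2C/+3G."""

    def __init__(self, records: list[MutationRecord]):
        self.records = records

    @classmethod
    def from_tsv(cls, path) -> "PsiGroupComparison":
        df = pd.read_csv(path, sep="\t")
        records = [MutationRecord(
            gene=str(r.gene), exon=str(r.exon), exon_start3=str(r.exon_start3),
            psi=float(r.psi), notes=str(getattr(r, "source_note", "")))
            for r in df.itertuples(index=False)]
        return cls(records)

    def fit(self) -> "PsiGroupComparisonResults":
        return PsiGroupComparisonResults(records=self.records,
                                         result=group_compare(self.records))


@dataclass
class PsiGroupComparisonResults:
    records: list[MutationRecord]
    result: dict

    def summary(self) -> str:
        r = self.result
        lines = ["Exon-start +1G mutation PSI comparison", "=" * 48,
                 f"n = {r['n_total']}; with +2C/+3G: "
                 f"{r['group_sizes'].get(True, 0)}, without: "
                 f"{r['group_sizes'].get(False, 0)}",
                 "members with +2C/+3G: " + ", ".join(r["members_with_context"])]
        for flag, s in sorted(r["summaries"].items(), reverse=True):
            label = "+2C/+3G" if flag else "other  "
            lines.append(
                f"  {label}: n={s['n']} median={s['median']:.1f} "
                f"[{s['min']:.0f}, {s['q1']:.1f}, {s['q3']:.1f}, {s['max']:.0f}]")
        if r.get("tests"):
            t = r["tests"]
            lines.append(f"Welch ANOVA F = {t['welch_F']:.3f}, p = {t['welch_p']:.4g}")
            lines.append(f"Kruskal-Wallis H = {t['kruskal_H']:.3f}, "
                         f"p = {t['kruskal_p']:.4g}")
        elif r.get("notice"):
            lines.append(r["notice"])
        return "\n".join(lines)
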