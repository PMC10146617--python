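"""Group statistics on pattern energies and signature selection.

Four comparisons are run for every (site, network, pattern) cell:

1. controls pre- vs post-TMS (paired t-test),
2. patients pre- vs post-TMS (paired t-test),
3. controls vs patients, pre-TMS (Welch two-sample t-test),
4. controls vs patients, post-TMS (Welch two-sample t-test).

Within-group comparisons are paired because the same subjects contribute
both conditions; between-group comparisons use Welch's correction since
the groups differ in size and possibly variance.  All tests are
two-sided.

Significance is gated per network by the Bonferroni rule p < alpha / n,
where n is the number of short-selected (stable) patterns for that
network's landscape and alpha = 0.05.  A second, stricter relevance gate
(p <= 5e-5) marks the most reliable signatures.  Effect sizes are
Cohen's d: pooled-SD for independent arms, mean(diff)/sd(diff) for
paired ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "COMPARISON_KINDS",
    "ComparisonSpec",
    "SignatureRecord",
    "run_comparisons",
    "enumerate_specs",
    "bonferroni_gate",
    "cohens_d",
    "build_signature_table",
    "render_report",
]

COMPARISON_KINDS = (
    "controls_pre_vs_post",
    "patients_pre_vs_post",
    "pre_controls_vs_patients",
    "post_controls_vs_patients",
)

_PAIRED_KINDS = {"controls_pre_vs_post", "patients_pre_vs_post"}

DEFAULT_ALPHA = 0.05
DEFAULT_RELEVANCE_P = 5e-5


@dataclass(frozen=True)
class ComparisonSpec:
    """One (comparison kind, network, pattern, site) cell."""

    kind: str
    network: str
    pattern_code: int
    site: str

    def __post_init__(self) -> None:
        if self.kind not in COMPARISON_KINDS:
            raise ValueError(f"unknown comparison kind {self.kind!r}")

    @property
    def paired(self) -> bool:
        return self.kind in _PAIRED_KINDS


@dataclass
class SignatureRecord:
    """Test result for one comparison cell, with Bonferroni bookkeeping.

    ``bonferroni_threshold`` and the pass flags are filled in by
    :func:`bonferroni_gate`; ``testable`` is False when a cell had fewer
    than two observations per arm (the record is kept, not dropped).
    """

    spec: ComparisonSpec
    p_value: float = float("nan")
    t_statistic: float = float("nan")
    cohens_d: float = float("nan")
    n_a: int = 0
    n_b: int = 0
    testable: bool = True
    note: str = ""
    bonferroni_threshold: float = float("nan")
    passes_bonferroni: bool = False
    passes_relevance: bool = False


def cohens_d(arm_a, arm_b, paired: bool = False) -> float:
    """Standardized mean difference.

    Unpaired: (mean_a - mean_b) / pooled SD (n-1 denominators).  Paired:
    mean(a - b) / sd(a - b).  Identical arms give 0; a nonzero mean
    difference with zero spread gives signed infinity (degenerate, with a
    warning).
    """
    a = np.asarray(arm_a, dtype=float)
    b = np.asarray(arm_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per arm")
    if paired:
        if a.size != b.size:
            raise ValueError("paired arms must have equal length")
        diff = a - b
        num, denom = diff.mean(), diff.std(ddof=1)
    else:
        num = a.mean() - b.mean()
        pooled_var = (
            (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
        ) / (a.size + b.size - 2)
        denom = np.sqrt(pooled_var)
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        warnings.warn(
            "zero variance with nonzero mean difference; Cohen's d is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.sign(num) * np.inf)
    return float(num / denom)


def _arms(energies: pd.DataFrame, spec: ComparisonSpec):
    """Extract the two observation arrays for one comparison cell.

    Paired arms are aligned on subject id.  Returns (a, b, note) where a
    note explains an untestable cell.
    """
    cell = energies[
        (energies["network"] == spec.network)
        & (energies["pattern_code"] == spec.pattern_code)
        & (energies["site"] == spec.site)
    ]
    if spec.paired:
        group = "controls" if spec.kind.startswith("controls") else "patients"
        sub = cell[cell["group"] == group]
        wide = sub.pivot_table(index="subject", columns="condition", values="energy")
        if "pre" not in wide.columns or "post" not in wide.columns:
            return None, None, "missing pre or post condition"
        wide = wide.dropna(subset=["pre", "post"])
        return wide["pre"].to_numpy(), wide["post"].to_numpy(), ""
    condition = "pre" if spec.kind.startswith("pre") else "post"
    sub = cell[cell["condition"] == condition]
    a = sub.loc[sub["group"] == "controls", "energy"].to_numpy()
    b = sub.loc[sub["group"] == "patients", "energy"].to_numpy()
    return a, b, ""


def run_comparisons(
    energies: pd.DataFrame, specs: Iterable[ComparisonSpec]
) -> list[SignatureRecord]:
    """Run the t-test for each comparison spec against the energies table.

    ``energies`` is the tidy frame produced by
    :func:`tmslandscape.landscape.subject_energies`.  Cells with fewer
    than two observations per arm are flagged untestable rather than
    silently dropped.  Arms with zero variance and zero mean difference
    yield p = 1 (no evidence of an effect) with a note.
    """
    records = []
    for spec in specs:
        rec = SignatureRecord(spec=spec)
        a, b, note = _arms(energies, spec)
        if a is None or len(a) < 2 or len(b) < 2:
            rec.testable = False
            rec.note = note or "fewer than 2 observations per arm"
            records.append(rec)
            continue
        rec.n_a, rec.n_b = len(a), len(b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if spec.paired:
                if np.allclose(a, b):
                    rec.p_value, rec.t_statistic = 1.0, 0.0
                    rec.note = "zero-variance differences"
                else:
                    t, p = sps.ttest_rel(a, b)
                    rec.t_statistic, rec.p_value = float(t), float(p)
            else:
                if np.var(a) == 0.0 and np.var(b) == 0.0 and a.mean() == b.mean():
                    rec.p_value, rec.t_statistic = 1.0, 0.0
                    rec.note = "zero-variance arms"
                else:
                    t, p = sps.ttest_ind(a, b, equal_var=False)
                    rec.t_statistic, rec.p_value = float(t), float(p)
            rec.cohens_d = cohens_d(a, b, paired=spec.paired)
        records.append(rec)
    return records


def enumerate_specs(
    selected: Mapping[tuple[str, str], Sequence[int]]
) -> list[ComparisonSpec]:
    """All four comparison kinds for every selected (site, network) pattern.

    ``selected`` maps (site, network) to that landscape's short-selected
    pattern codes.
    """
    specs = []
    for (site, network), codes in selected.items():
        for code in codes:
            for kind in COMPARISON_KINDS:
                specs.append(
                    ComparisonSpec(
                        kind=kind, network=network, pattern_code=int(code), site=site
                    )
                )
    return specs


def bonferroni_gate(
    records: list[SignatureRecord],
    alpha: float = DEFAULT_ALPHA,
    relevance_p: float = DEFAULT_RELEVANCE_P,
    n_patterns: Mapping[tuple[str, str], int] | None = None,
    pool_sites: bool = False,
) -> list[SignatureRecord]:
    """Set Bonferroni thresholds and pass flags in place (and return them).

    The per-network threshold is alpha / n with n the number of selected
    patterns for that (site, network) landscape - or pooled across sites
    with ``pool_sites=True``.  ``n_patterns`` may override the counts
    derived from the records.  ``passes_relevance`` additionally requires
    p <= ``relevance_p``.
    """
    if n_patterns is None:
        n_patterns = {}
        for rec in records:
            key = (rec.spec.site, rec.spec.network)
            n_patterns.setdefault(key, set()).add(rec.spec.pattern_code)
        n_patterns = {key: len(codes) for key, codes in n_patterns.items()}
    if pool_sites:
        pooled: dict[str, int] = {}
        for (site, network), n in n_patterns.items():
            pooled[network] = pooled.get(network, 0) + n
        lookup = lambda site, network: pooled[network]
    else:
        lookup = lambda site, network: n_patterns[(site, network)]

    for rec in records:
        n = lookup(rec.spec.site, rec.spec.network)
        if n == 0:
            raise ValueError(
                f"no selected patterns for network {rec.spec.network!r} "
                f"at site {rec.spec.site!r}"
            )
        rec.bonferroni_threshold = alpha / n
        if rec.testable and np.isfinite(rec.p_value):
            rec.passes_bonferroni = rec.p_value < rec.bonferroni_threshold
            rec.passes_relevance = (
                rec.passes_bonferroni and rec.p_value <= relevance_p
            )
        else:
            rec.passes_bonferroni = rec.passes_relevance = False
    return records


def build_signature_table(
    records: list[SignatureRecord],
    networks: Mapping[str, "object"] | None = None,
) -> pd.DataFrame:
    """Tidy signature table, one row per comparison record.

    When network definitions are supplied, each pattern is also rendered
    as 'Region=+1; ...' in region order, mirroring the constituent-region
    column layout of the published signature tables.
    """
    columns = [
        "site",
        "network",
        "pattern_code",
        "pattern",
        "regions",
        "comparison",
        "n_controls_arm",
        "n_patients_arm",
        "p_value",
        "bonferroni_threshold",
        "passes_bonferroni",
        "passes_relevance",
        "cohens_d",
        "testable",
        "note",
    ]
    rows = []
    for rec in records:
        spec = rec.spec
        pattern_str = regions_str = ""
        if networks is not None and spec.network in networks:
            regions = networks[spec.network].regions
            bits = [(spec.pattern_code >> i) & 1 for i in range(len(regions))]
            pattern_str = "".join("+" if b else "-" for b in bits)
            regions_str = "; ".join(
                f"{r}={'+1' if b else '-1'}" for r, b in zip(regions, bits)
            )
        rows.append(
            {
                "site": spec.site,
                "network": spec.network,
                "pattern_code": spec.pattern_code,
                "pattern": pattern_str,
                "regions": regions_str,
                "comparison": spec.kind,
                "n_controls_arm": rec.n_a,
                "n_patients_arm": rec.n_b,
                "p_value": rec.p_value,
                "bonferroni_threshold": rec.bonferroni_threshold,
                "passes_bonferroni": rec.passes_bonferroni,
                "passes_relevance": rec.passes_relevance,
                "cohens_d": rec.cohens_d,
                "testable": rec.testable,
                "note": rec.note,
            }
        )
    return pd.DataFrame(rows, columns=columns)


def render_report(table: pd.DataFrame, only_passing: bool = False) -> str:
    """Human-readable per-network report of the signature table."""
    if table.empty:
        return "No comparison records.\n"
    if only_passing:
        table = table[table["passes_bonferroni"]]
    lines = []
    for (site, network), sub in table.groupby(["site", "network"], sort=True):
        lines.append(f"== {network} network, {site} stimulation ==")
        for _, row in sub.iterrows():
            flags = []
            if row["passes_bonferroni"]:
                flags.append("BONFERRONI")
            if row["passes_relevance"]:
                flags.append("RELEVANT")
            flag_str = f" [{', '.join(flags)}]" if flags else ""
            lines.append(
                f"  pattern {row['pattern'] or row['pattern_code']}: "
                f"{row['comparison']}  p={row['p_value']:.3g} "
                f"(threshold {row['bonferroni_threshold']:.3g}), "
                f"d={row['cohens_d']:.2f}{flag_str}"
            )
        lines.append("")
    return "\n".join(lines)
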