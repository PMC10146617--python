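"""End-to-end orchestration: simulate -> preprocess -> localize -> landscape -> stats.

:class:`RunConfig` captures everything a run needs (cohorts, preprocessing
parameters, landscape and statistics settings, one global seed) and is
fully YAML-serializable; :func:`run_all` executes the whole study and,
when an output directory is given, persists the configuration echo, the
energies and signature tables, a text report, and a checksummed manifest.

:func:`run_reduced_study` is a stripped-down variant that skips the
EEG/forward/inverse stages and feeds exact Ising samples straight into
the landscape and statistics machinery - the workhorse for large
replication studies such as null calibration, where re-simulating scalp
data thousands of times would add nothing but runtime.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landscape as ls
from . import stats as st
from .localize import RoiSeries, SloretaSolver, aggregate_rois, alpha_band_power
from .networks import NetworkDefinition, default_networks
from .preprocess import preprocess_pipeline
from .synthetic import (
    DEFAULT_TARGET_NETWORKS,
    CohortSpec,
    GroundTruth,
    ToyHeadModel,
    iter_cohort,
    make_ground_truth,
    make_head_model,
    sample_ising_series,
)

__all__ = ["SiteConfig", "RunConfig", "RunResult", "run_all", "run_reduced_study"]


@dataclass
class SiteConfig:
    """Cohort sizes and target network for one stimulation site."""

    site_label: str
    n_patients: int
    n_controls: int
    n_trials_per_subject: int = 60
    target_network: str | None = None  # None -> site default

    def resolve_target(self) -> str:
        return self.target_network or DEFAULT_TARGET_NETWORKS[self.site_label]


@dataclass
class RunConfig:
    """Serializable configuration of a full synthetic study."""

    seed: int = 0
    sites: list[SiteConfig] = field(
        default_factory=lambda: [
            SiteConfig("left_motor", 22, 27),
            SiteConfig("left_prefrontal", 9, 18),
            SiteConfig("vermis", 12, 25),
        ]
    )
    # synthesis
    n_voxels: int = 52
    planted_effect: float = 0.0
    dwell_ms: float = 100.0
    a_active: float = 8.0
    a_inactive: float = 1.0
    a_background: float = 0.5
    noise_sigma_uv: float = 2.0
    artifact_fraction: float = 0.1
    # preprocessing
    reject_uv: float = 75.0
    band_hz: tuple[float, float] = (1.0, 50.0)
    decim: int = 2
    # localization
    alpha_band_hz: tuple[float, float] = (8.0, 12.0)
    reg_alpha: float | str = "auto"
    # landscape
    analyzed_networks: list[str] | None = None  # None -> target network per site
    stable_k: int | None = None  # None -> all local minima
    tol_moment: float = 1e-4
    l2_group: float = 1e-4
    l2_subject: float = 1e-2
    theta_max: float = 20.0
    # statistics
    alpha: float = 0.05
    relevance_p: float = 5e-5
    networks_yaml: str | None = None  # None -> packaged defaults

    def __post_init__(self) -> None:
        self.sites = [
            SiteConfig(**s) if isinstance(s, dict) else s for s in self.sites
        ]
        self.band_hz = tuple(self.band_hz)
        self.alpha_band_hz = tuple(self.alpha_band_hz)
        if not self.sites:
            raise ValueError("config needs at least one site")
        for site in self.sites:
            if site.n_patients <= 0 or site.n_controls <= 0:
                raise ValueError(
                    f"site {site.site_label!r}: subject counts must be positive"
                )

    def networks(self) -> dict[str, NetworkDefinition]:
        from .networks import load_networks

        if self.networks_yaml:
            return load_networks(self.networks_yaml)
        return default_networks()

    def to_yaml(self, path=None) -> str:
        payload = asdict(self)
        payload["band_hz"] = list(self.band_hz)
        payload["alpha_band_hz"] = list(self.alpha_band_hz)
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


@dataclass
class RunResult:
    """Everything a full run produced, in memory."""

    config: RunConfig
    head: ToyHeadModel
    truths: dict[str, GroundTruth]
    roi_series: dict[str, list[RoiSeries]]
    selected: dict[tuple[str, str], list[int]]
    energies: pd.DataFrame
    records: list[st.SignatureRecord]
    table: pd.DataFrame

    @property
    def passing(self) -> pd.DataFrame:
        return self.table[self.table["passes_bonferroni"]]


def _group_landscapes(
    series: list[RoiSeries],
    network: NetworkDefinition,
    *,
    l2: float,
    tol_moment: float,
    theta_max: float,
) -> dict[tuple[str, str], ls.EnergyLandscape]:
    """Fit one landscape per (group, condition) on concatenated subject data."""
    out = {}
    for group in ("patients", "controls"):
        for condition in ("pre", "post"):
            chunks = [
                ls.binarize(rs, network, condition).patterns
                for rs in series
                if rs.group == group
            ]
            patterns = np.vstack(chunks)
            model = ls.fit_maxent(
                patterns, l2=l2, tol_moment=tol_moment, theta_max=theta_max
            )
            out[(group, condition)] = ls.EnergyLandscape.from_model(model)
    return out


def _select_patterns(
    landscapes: dict[tuple[str, str], ls.EnergyLandscape], k: int | None
) -> list[int]:
    """Union of each landscape's stable states, sorted by code."""
    codes: set[int] = set()
    for scape in landscapes.values():
        codes.update(ls.find_stable_states(scape, k))
    return sorted(codes)


def run_all(config: RunConfig, out_dir=None) -> RunResult:
    """Execute the whole synthetic study described by *config*.

    Stages per site: synthesize the cohort, preprocess every subject to an
    ERP, invert with sLORETA, extract alpha-band ROI power, fit the four
    group-condition landscapes per analyzed network, select stable
    patterns, compute subject-wise energies, and run the gated
    comparisons.  Deterministic under a fixed config (same seed in, same
    tables out).
    """
    networks = config.networks()
    head = make_head_model(config.n_voxels, config.seed, networks=networks)
    solver = SloretaSolver(head, config.reg_alpha)

    truths: dict[str, GroundTruth] = {}
    roi_series: dict[str, list[RoiSeries]] = {}
    for site_cfg in config.sites:
        site = site_cfg.site_label
        target = site_cfg.resolve_target()
        if target not in networks:
            raise ValueError(f"site {site!r}: unknown target network {target!r}")
        truth = make_ground_truth(
            networks[target], planted_effect=config.planted_effect, seed=config.seed
        )
        truths[site] = truth
        spec = CohortSpec(
            n_patients=site_cfg.n_patients,
            n_controls=site_cfg.n_controls,
            site_label=site,
            n_trials_per_subject=site_cfg.n_trials_per_subject,
            seed=config.seed,
        )
        series_list: list[RoiSeries] = []
        for subject in iter_cohort(
            spec,
            truth,
            head,
            dwell_ms=config.dwell_ms,
            a_active=config.a_active,
            a_inactive=config.a_inactive,
            a_background=config.a_background,
            noise_sigma_uv=config.noise_sigma_uv,
            artifact_fraction=config.artifact_fraction,
        ):
            try:
                erp = preprocess_pipeline(
                    subject.epochs,
                    reject_uv=config.reject_uv,
                    band_hz=config.band_hz,
                    decim=config.decim,
                )
                est = solver.apply(erp.data, fs_hz=erp.fs_hz)
                est = alpha_band_power(est, band_hz=config.alpha_band_hz)
                rs = aggregate_rois(
                    est,
                    head,
                    subject_id=subject.subject_id,
                    group=subject.group,
                    site=site,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage failure for subject {subject.subject_id!r} "
                    f"at site {site!r}: {exc}"
                ) from exc
            series_list.append(rs)
        roi_series[site] = series_list

    selected: dict[tuple[str, str], list[int]] = {}
    energy_frames = []
    for site_cfg in config.sites:
        site = site_cfg.site_label
        names = config.analyzed_networks or [site_cfg.resolve_target()]
        for name in names:
            network = networks[name]
            landscapes = _group_landscapes(
                roi_series[site],
                network,
                l2=config.l2_group,
                tol_moment=config.tol_moment,
                theta_max=config.theta_max,
            )
            codes = _select_patterns(landscapes, config.stable_k)
            selected[(site, name)] = codes
            energy_frames.append(
                ls.subject_energies(
                    roi_series[site],
                    network,
                    codes,
                    fit_kwargs={
                        "l2": config.l2_subject,
                        "tol_moment": config.tol_moment,
                        "theta_max": config.theta_max,
                    },
                )
            )
    energies = pd.concat(energy_frames, ignore_index=True)
    records = st.run_comparisons(energies, st.enumerate_specs(selected))
    st.bonferroni_gate(records, alpha=config.alpha, relevance_p=config.relevance_p)
    table = st.build_signature_table(records, networks)

    result = RunResult(
        config=config,
        head=head,
        truths=truths,
        roi_series=roi_series,
        selected=selected,
        energies=energies,
        records=records,
        table=table,
    )
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _persist(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out_dir / "config.yaml")
    result.energies.to_csv(out_dir / "energies.csv", index=False)
    result.table.to_csv(out_dir / "signatures.csv", index=False)
    (out_dir / "report.txt").write_text(st.render_report(result.table))
    selected_rows = [
        {"site": site, "network": network, "pattern_code": code}
        for (site, network), codes in result.selected.items()
        for code in codes
    ]
    pd.DataFrame(
        selected_rows, columns=["site", "network", "pattern_code"]
    ).to_csv(out_dir / "selected_patterns.csv", index=False)
    import json

    (out_dir / "ground_truth.json").write_text(
        json.dumps({s: t.to_jsonable() for s, t in result.truths.items()}, indent=2)
    )
    names = [
        "config.yaml",
        "energies.csv",
        "signatures.csv",
        "report.txt",
        "selected_patterns.csv",
        "ground_truth.json",
    ]
    manifest = pd.DataFrame(
        {
            "file": names,
            "sha256": [
                hashlib.sha256((out_dir / n).read_bytes()).hexdigest() for n in names
            ],
        }
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)


# ---------------------------------------------------------------------------
# reduced (pattern-level) replication study
# ---------------------------------------------------------------------------


def run_reduced_study(
    truth: GroundTruth,
    *,
    n_patients: int,
    n_controls: int,
    n_samples: int = 500,
    seed: int = 0,
    site_label: str = "left_motor",
    stable_k: int | None = None,
    l2_group: float = 1e-4,
    l2_subject: float = 1e-2,
    tol_moment: float = 1e-4,
    theta_max: float = 20.0,
    alpha: float = 0.05,
    relevance_p: float = 5e-5,
) -> tuple[list[st.SignatureRecord], list[int]]:
    """Landscape + statistics study on exact Ising samples (no EEG stages).

    Each subject-condition cell draws ``n_samples`` i.i.d. patterns from
    its ground-truth model; group landscapes are fitted on the
    concatenated group data, stable patterns selected, subject-level
    models fitted, and the gated comparisons run.  Returns the gated
    records and the selected pattern codes.
    """
    network = truth.network
    m = network.n_regions
    groups = [("patients", i) for i in range(n_patients)] + [
        ("controls", i) for i in range(n_controls)
    ]
    subject_patterns: list[tuple[str, str, dict[str, np.ndarray]]] = []
    for index, (group, i) in enumerate(groups):
        sid = f"{site_label}-{group[:3]}{i + 1:02d}"
        rng = np.random.default_rng([seed, 9001, index])
        cells = {
            cond: sample_ising_series(truth.models[(group, cond)], n_samples, rng)
            for cond in ("pre", "post")
        }
        subject_patterns.append((sid, group, cells))

    landscapes = {}
    for group in ("patients", "controls"):
        for condition in ("pre", "post"):
            chunks = [
                cells[condition]
                for _, g, cells in subject_patterns
                if g == group
            ]
            model = ls.fit_maxent(
                np.vstack(chunks),
                l2=l2_group,
                tol_moment=tol_moment,
                theta_max=theta_max,
            )
            landscapes[(group, condition)] = ls.EnergyLandscape.from_model(model)
    codes = _select_patterns(landscapes, stable_k)

    rows = []
    for sid, group, cells in subject_patterns:
        for condition in ("pre", "post"):
            model = ls.fit_maxent(
                cells[condition],
                l2=l2_subject,
                tol_moment=tol_moment,
                theta_max=theta_max,
            )
            for code in codes:
                rows.append(
                    {
                        "subject": sid,
                        "group": group,
                        "site": site_label,
                        "condition": condition,
                        "network": network.name,
                        "pattern_code": code,
                        "pattern_string": ls.pattern_string(code, m),
                        "energy": ls.energy(model, ls.code_to_spins(code, m)),
                    }
                )
    energies = pd.DataFrame(rows)
    selected = {(site_label, network.name): codes}
    records = st.run_comparisons(energies, st.enumerate_specs(selected))
    st.bonferroni_gate(records, alpha=alpha, relevance_p=relevance_p)
    return records, codes
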