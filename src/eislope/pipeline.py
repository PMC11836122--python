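"""End-to-end orchestration: recordings -> features -> statistics.

The pipeline composes the stages in study order: preprocessing, sliding
8-s/75%-overlap windowing, IRASA decomposition, band-wise slope fits, RSN
aggregation, per-subject temporal features (mu, sigma), and the statistical
battery. Synthetic recordings are generated at the target rate with full
spectral content and no artifacts, so in synthetic mode the resample/filter
stage is skipped and only referencing + epoch selection apply.

FDR families follow the reference analysis design: per-channel bimodality contrasts form
one family per group (all channels, one band pair); RSN group comparisons
form one family of networks per measure x band; clinical correlations are
deliberately not multiplicity-adjusted.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import InvalidArgumentError, Recording
from .io import read_recording, write_results
from .irasa import IrasaConfig
from .montage import load_rsn_map
from .preprocess import (
    PreprocessConfig,
    common_average_reference,
    preprocess,
    select_epoch,
)
from .slopes import (
    DEFAULT_BANDS,
    aggregate_rsn,
    slope_timeseries,
    temporal_summary,
)
from .stats import (
    TestResult,
    bh_fdr,
    correlate_clinical,
    paired_bimodality_test,
    residualize_confounds,
    two_sample_test,
)
from .synth import CohortSpec, gen_cohort

CONFOUNDS = ("age", "sex", "education_years", "illness_duration", "cpz")


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    seed: int = 0
    out_dir: str = "eislope-out"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_files: tuple[str, ...] = ()
    cohort_table: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    irasa: IrasaConfig = field(default_factory=IrasaConfig)
    window: float = 8.0
    overlap: float = 0.75
    rsn_map_path: str | None = None
    engine: str = "poly"
    alpha: float = 0.05
    q: float = 0.05
    gate: str = "auto"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise InvalidArgumentError("mode must be 'synthetic' or 'files'")
        self.irasa.validate_fs(self.preprocess.target_fs)
        if not 0 <= self.overlap < 1:
            raise InvalidArgumentError("overlap must be in [0, 1)")
        if self.preprocess.epoch_seconds < self.window:
            raise InvalidArgumentError("epoch shorter than one analysis window")
        if self.mode == "files" and not self.input_files:
            raise InvalidArgumentError("files mode needs input_files")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        nested = {
            "cohort": CohortSpec,
            "preprocess": PreprocessConfig,
            "irasa": IrasaConfig,
        }
        for f in fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name in nested and isinstance(v, dict):
                v = {
                    k: tuple(x) if isinstance(x, list) else x for k, x in v.items()
                }
                v = nested[f.name](**v)
            elif isinstance(v, list):
                v = tuple(v)
            kw[f.name] = v
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _subject_seed(global_seed: int, subject_id: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{subject_id}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def subject_features(
    rec: Recording,
    rsn_map: dict[str, str],
    icfg: IrasaConfig | None = None,
    bands=DEFAULT_BANDS,
    window: float = 8.0,
    overlap: float = 0.75,
    engine: str = "poly",
):
    """Slope series -> (RSN features, per-channel temporal means)."""
    series = slope_timeseries(
        rec, icfg, bands=bands, window=window, overlap=overlap, engine=engine
    )
    feats = temporal_summary(aggregate_rsn(series, rsn_map))
    chan_mu = series.beta.mean(axis=1)  # (n_ch, n_band)
    return feats, series.channel_labels, chan_mu


def analyze_cohort(
    recordings: list[Recording],
    rsn_map: dict[str, str] | None = None,
    icfg: IrasaConfig | None = None,
    bands=DEFAULT_BANDS,
    window: float = 8.0,
    overlap: float = 0.75,
    engine: str = "poly",
    car: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject features for already-preprocessed recordings.

    Returns (features, channel_mu): tidy tables of RSN-level mu/sigma and of
    per-channel temporal-mean slopes.
    """
    rsn_map = rsn_map or load_rsn_map()
    feat_frames, chan_rows = [], []
    for rec in recordings:
        if car and rec.n_channels > 1:
            rec = common_average_reference(rec)
        feats, chans, chan_mu = subject_features(
            rec, rsn_map, icfg, bands, window, overlap, engine
        )
        fr = feats.to_frame()
        fr.insert(1, "group", rec.group)
        feat_frames.append(fr)
        for i, ch in enumerate(chans):
            for j, band in enumerate(feats.band_names):
                chan_rows.append(
                    dict(
                        subject_id=rec.subject_id,
                        group=rec.group,
                        channel=ch,
                        band=band,
                        mu=chan_mu[i, j],
                    )
                )
    return pd.concat(feat_frames, ignore_index=True), pd.DataFrame(chan_rows)


def _result_row(level, scope, measure, band, res: TestResult) -> dict:
    return dict(
        level=level,
        scope=scope,
        measure=measure,
        band=band,
        test=res.name,
        statistic=res.statistic,
        p=res.p,
        p_adjusted=res.p_adjusted,
        significant=res.significant,
        n=str(res.n),
        branch=res.branch,
    )


def rsn_group_tests(
    features: pd.DataFrame,
    measure: str,
    band: str,
    q: float = 0.05,
    gate: str = "auto",
) -> pd.DataFrame:
    """Two-sample group tests per network for one measure x band family,
    BH-adjusted across the networks."""
    groups = sorted(features["group"].unique())
    if len(groups) != 2:
        raise InvalidArgumentError(f"need exactly 2 groups, got {groups}")
    sub = features[features["band"] == band]
    networks = list(dict.fromkeys(sub["network"]))
    results = []
    for net in networks:
        cell = sub[sub["network"] == net]
        a = cell.loc[cell["group"] == groups[0], measure].to_numpy()
        b = cell.loc[cell["group"] == groups[1], measure].to_numpy()
        results.append(two_sample_test(a, b, gate=gate))
    p_adj, reject = bh_fdr([r.p for r in results], q)
    rows = []
    for net, res, pa, rej in zip(networks, results, p_adj, reject):
        res.p_adjusted = float(pa)
        res.significant = bool(rej)
        rows.append(_result_row("network", net, measure, band, res))
    return pd.DataFrame(rows)


def bimodality_tests(
    channel_mu: pd.DataFrame,
    group: str,
    q: float = 0.05,
    gate: str = "auto",
    bands: tuple[str, str] = ("lo", "hi"),
) -> pd.DataFrame:
    """Per-channel paired contrast of mu(beta_lo) vs mu(beta_hi) within one
    group; one FDR family across all channels."""
    sub = channel_mu[channel_mu["group"] == group]
    piv = sub.pivot_table(
        index=["subject_id", "channel"], columns="band", values="mu"
    )
    channels = list(dict.fromkeys(sub["channel"]))
    results = []
    for ch in channels:
        cell = piv.xs(ch, level="channel")
        results.append(
            paired_bimodality_test(
                cell[bands[0]].to_numpy(), cell[bands[1]].to_numpy(), gate=gate
            )
        )
    p_adj, reject = bh_fdr([r.p for r in results], q)
    rows = []
    for ch, res, pa, rej in zip(channels, results, p_adj, reject):
        res.p_adjusted = float(pa)
        res.significant = bool(rej)
        rows.append(
            _result_row("channel", f"{group}:{ch}", "mu_lo_vs_hi", "lo/hi", res)
        )
    return pd.DataFrame(rows)


def clinical_correlation(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    network: str = "DA",
    band: str = "hi",
    measure: str = "sigma",
    score: str = "panss_pos",
    group: str | None = None,
    confounds: tuple[str, ...] = CONFOUNDS,
    gate: str = "auto",
) -> TestResult:
    """Confound-residualized correlation between one RSN feature and one
    clinical score within the patient group.

    Both the feature and the score are residualized on the confound columns
    (sex coded 0/1) before the normality-gated correlation.
    """
    if group is None:
        group = cohort.loc[cohort[score].notna(), "group"].iloc[0]
    feat = features[
        (features["network"] == network)
        & (features["band"] == band)
        & (features["group"] == group)
    ][["subject_id", measure]]
    tab = cohort[cohort["group"] == group].merge(feat, on="subject_id")
    X = np.column_stack(
        [
            (tab[c] == tab[c].iloc[0]).astype(float)
            if tab[c].dtype == object
            else tab[c].astype(float)
            for c in confounds
        ]
    )
    x = residualize_confounds(tab[measure].to_numpy(float), X)
    y = residualize_confounds(tab[score].to_numpy(float), X)
    return correlate_clinical(x, y, gate=gate)


def cohort_statistics(
    features: pd.DataFrame,
    channel_mu: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
    q: float = 0.05,
    gate: str = "auto",
) -> pd.DataFrame:
    """The full battery: RSN group tests for mu and sigma in every band,
    per-channel bimodality per group, and — when a cohort table with PANSS
    scores is given — clinical correlations for features whose group test
    survived FDR."""
    frames = []
    bands = list(dict.fromkeys(features["band"]))
    for measure in ("mu", "sigma"):
        for band in bands:
            frames.append(rsn_group_tests(features, measure, band, q, gate))
    for group in sorted(features["group"].unique()):
        if {"lo", "hi"} <= set(bands):
            frames.append(bimodality_tests(channel_mu, group, q, gate))
    stats_df = pd.concat(frames, ignore_index=True)

    if cohort is not None and "panss_pos" in cohort:
        hits = stats_df[
            (stats_df["level"] == "network") & (stats_df["significant"] == True)  # noqa: E712
        ]
        rows = []
        for _, hit in hits.iterrows():
            for score in ("panss_pos", "panss_neg", "panss_gen", "panss_sum"):
                res = clinical_correlation(
                    features,
                    cohort,
                    network=hit["scope"],
                    band=hit["band"],
                    measure=hit["measure"],
                    score=score,
                    gate=gate,
                )
                res.at_alpha(0.05)
                rows.append(
                    _result_row(
                        "clinical",
                        f"{hit['scope']}~{score}",
                        hit["measure"],
                        hit["band"],
                        res,
                    )
                )
        if rows:
            stats_df = pd.concat(
                [stats_df, pd.DataFrame(rows)], ignore_index=True
            )
    return stats_df


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute the configured pipeline and write features.csv, stats.csv,
    and manifest.json to cfg.out_dir."""
    cfg.validate()
    warnings_log: list[str] = []
    if cfg.mode == "synthetic":
        cspec = cfg.cohort
        if cspec.seed != cfg.seed:
            cspec = CohortSpec(**{**asdict(cspec), "seed": cfg.seed})
        recordings, cohort = gen_cohort(cspec)
        # synthetic data is generated at target fs, full-band, artifact-free:
        # referencing + epoch selection only
        prepped = []
        for rec in recordings:
            rec = common_average_reference(rec)
            if rec.duration > cfg.preprocess.epoch_seconds:
                rec = select_epoch(
                    rec,
                    cfg.preprocess.epoch_seconds,
                    _subject_seed(cfg.seed, rec.subject_id),
                )
            prepped.append(rec)
    else:
        cohort = (
            pd.read_csv(cfg.cohort_table) if cfg.cohort_table else None
        )
        prepped = []
        for f in cfg.input_files:
            rec = read_recording(f)
            if cohort is not None:
                row = cohort[cohort["subject_id"] == rec.subject_id]
                if len(row):
                    rec.group = str(row["group"].iloc[0])
            pcfg = cfg.preprocess
            pcfg = PreprocessConfig(
                **{
                    **asdict(pcfg),
                    "epoch_seed": _subject_seed(cfg.seed, rec.subject_id),
                }
            )
            prepped.append(preprocess(rec, pcfg))

    rsn_map = load_rsn_map(cfg.rsn_map_path)
    features, channel_mu = analyze_cohort(
        prepped,
        rsn_map,
        cfg.irasa,
        window=cfg.window,
        overlap=cfg.overlap,
        engine=cfg.engine,
        car=False,  # referencing already applied above
    )
    stats_df = cohort_statistics(features, channel_mu, cohort, cfg.q, cfg.gate)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "n_subjects": len(prepped),
        "rows": {"features": len(features), "stats": len(stats_df)},
        "warnings": warnings_log,
    }
    return write_results(features, stats_df, manifest, cfg.out_dir)
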