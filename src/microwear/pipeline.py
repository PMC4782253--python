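"""End-to-end study orchestration: surfaces → parameters → group inference.

The pipeline mirrors a habitat-comparison study design: every specimen
surface is leveled and reduced to the 30 areal texture parameters, the
groups are summarized (untrimmed mean and SD, the conventional
descriptive presentation), compared with the trimmed-means omnibus and
pairwise batteries plus Cliff's confirmation, and finally ranked by
dietary abrasiveness over the consensus-significant parameters.

Group dropout is per parameter: a group contributing fewer than two
usable values for a parameter (or degenerating to zero winsorized
variance) is dropped from that parameter's tests only, with the reason
logged; the omnibus ν1 then reflects the reduced group count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DegeneracyError, ValidationError
from .parameters import compute_all
from .robust import (
    CliffResult,
    PairwiseResult,
    StatsConfig,
    cliff_delta,
    consensus,
    lincon_pairwise,
    welch_yuen_omnibus,
)
from .surface import (
    PARAM_ORDER,
    HeightMap,
    read_height_map,
    read_parameter_table,
    write_height_map,
    write_parameter_table,
)
from .synthetic import HABITAT_PRESETS, HabitatPreset, SurfaceSpec, sample_habitat

__all__ = [
    "StudyConfig",
    "StudyReport",
    "Ranking",
    "run_study",
    "descriptives",
    "compare_parameters",
    "rank_abrasiveness",
    "simulate_surfaces",
    "compute_parameter_table",
]

log = logging.getLogger("microwear")


@dataclass
class StudyConfig:
    """Configuration of one study run.

    Exactly one of ``manifest`` (CSV with columns ``file``, ``format``,
    ``specimen_id``, ``group_label``) or ``simulate`` (dict with keys
    ``seed`` and optionally ``presets`` — list of preset names or mapping
    name → ``{mean_sa, sd_sa, n}`` — and ``spec`` overrides for the
    surface generator) must be given.
    """

    manifest: Optional[str] = None
    simulate: Optional[dict] = None
    stats: StatsConfig = field(default_factory=StatsConfig)
    out_dir: Optional[str] = None
    level: bool = True
    iso_overrides: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.simulate is None):
            raise ValidationError(
                "exactly one of manifest or simulate must be provided"
            )


@dataclass
class Ranking:
    """Ordered tie classes of groups, from highest to lowest abrasiveness."""

    classes: List[List[str]] = field(default_factory=list)
    indeterminate: bool = False

    def format(self) -> str:
        if self.indeterminate:
            return "indeterminate"
        return " > ".join(" / ".join(c) for c in self.classes)


@dataclass
class StudyReport:
    """All study outputs: per-specimen parameters, the three tables, the
    consensus-significant parameter list and the abrasiveness ranking."""

    parameters: pd.DataFrame
    descriptive: pd.DataFrame
    omnibus: pd.DataFrame
    pairwise: pd.DataFrame
    significant: List[str]
    ranking: Ranking
    skipped: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stages


def descriptives(df: pd.DataFrame, params: Sequence[str] = PARAM_ORDER) -> pd.DataFrame:
    """Per group × parameter: n of non-missing values, mean, sample SD.

    Uses untrimmed arithmetic mean and SD (denominator n−1); SD is NaN for
    single-specimen cells.
    """
    rows = []
    for group, sub in df.groupby("group_label", sort=True):
        for p in params:
            vals = sub[p].dropna().to_numpy(dtype=float)
            rows.append({
                "group": group,
                "parameter": p,
                "n": vals.size,
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "sd": float(np.std(vals, ddof=1)) if vals.size >= 2 else np.nan,
            })
    return pd.DataFrame(rows, columns=["group", "parameter", "n", "mean", "sd"])


def _usable_groups(
    df: pd.DataFrame, param: str, cfg: StatsConfig
) -> Tuple[Dict[str, np.ndarray], List[str]]:
    """Group samples usable for this parameter's tests, plus drop reasons."""
    groups: Dict[str, np.ndarray] = {}
    reasons: List[str] = []
    for label, sub in df.groupby("group_label", sort=True):
        vals = sub[param].dropna().to_numpy(dtype=float)
        n = vals.size
        g = int(np.floor(cfg.gamma * n))
        if n < 2 or n - 2 * g < 2:
            reasons.append(f"{label}: only {n} value(s) for {param}")
            continue
        if np.ptp(vals) == 0.0:
            reasons.append(f"{label}: zero variance for {param}")
            continue
        groups[label] = vals
    return groups, reasons


def compare_parameters(
    df: pd.DataFrame,
    cfg: StatsConfig = StatsConfig(),
    params: Sequence[str] = PARAM_ORDER,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[str], Dict[str, str]]:
    """Omnibus and pairwise-consensus tables for a parameter table.

    Returns ``(omnibus, pairwise, significant_parameters, skipped)`` where
    the tables mirror the usual presentation: one omnibus row per
    parameter (Ft, P, nu1, nu2) and one pairwise row per parameter × group
    pair (t, P, df, Cliff's delta with CI, consensus flag).
    """
    omnibus_rows = []
    pairwise_rows = []
    significant: List[str] = []
    skipped: Dict[str, str] = {}
    for p in params:
        groups, reasons = _usable_groups(df, p, cfg)
        if reasons:
            log.info("parameter %s: dropped %s", p, "; ".join(reasons))
        if len(groups) < 2:
            skipped[p] = "; ".join(reasons) or "fewer than 2 usable groups"
            continue
        try:
            om = welch_yuen_omnibus(list(groups.values()), cfg, labels=list(groups))
        except DegeneracyError as e:
            skipped[p] = str(e)
            continue
        omnibus_rows.append({
            "parameter": p, "Ft": om.Ft, "P": om.P, "nu1": om.nu1, "nu2": om.nu2,
        })
        lincon = lincon_pairwise(groups, cfg)
        cliffs = {
            r.pair: cliff_delta(groups[r.pair[0]], groups[r.pair[1]], cfg)
            for r in lincon
        }
        merged, any_sig = consensus(lincon, cliffs, cfg)
        if any_sig:
            significant.append(p)
        for r in merged:
            pairwise_rows.append({
                "parameter": p, "group_1": r.pair[0], "group_2": r.pair[1],
                "t": r.t, "P": r.P, "df": r.df, "delta": r.delta,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "cliff_significant": r.cliff_significant,
                "consensus": r.consensus,
            })
    omnibus = pd.DataFrame(
        omnibus_rows, columns=["parameter", "Ft", "P", "nu1", "nu2"]
    )
    pairwise = pd.DataFrame(
        pairwise_rows,
        columns=["parameter", "group_1", "group_2", "t", "P", "df", "delta",
                 "ci_low", "ci_high", "cliff_significant", "consensus"],
    )
    return omnibus, pairwise, significant, skipped


def rank_abrasiveness(
    desc: pd.DataFrame,
    significant: Sequence[str],
    pairwise: pd.DataFrame,
) -> Ranking:
    """Rank groups by abrasiveness over the consensus-significant parameters.

    For each consensus-significant parameter the groups are ranked by
    group mean (rank 1 = highest); ranks are averaged across parameters
    and the groups ordered by mean rank.  Two adjacent groups fall into
    the same tie class when no parameter separates them by consensus and
    they are separated from exactly the same third parties — so a pattern
    where only the extremes differ yields extreme singleton classes around
    one intermediate tie class.
    """
    if not significant:
        return Ranking(indeterminate=True)
    wide = desc.pivot(index="group", columns="parameter", values="mean")
    groups = list(wide.index)
    ranks = np.zeros(len(groups))
    for p in significant:
        ranks += rankdata(-wide[p].to_numpy(dtype=float), method="average")
    mean_rank = ranks / len(significant)
    order = [g for _, g in sorted(zip(mean_rank, groups))]

    sep: Dict[str, set] = {g: set() for g in groups}
    sig_pairs = pairwise[pairwise["consensus"] & pairwise["parameter"].isin(significant)]
    for _, row in sig_pairs.iterrows():
        sep[row["group_1"]].add(row["group_2"])
        sep[row["group_2"]].add(row["group_1"])

    def same_class(a: str, b: str) -> bool:
        return (b not in sep[a]) and (sep[a] - {b}) == (sep[b] - {a})

    classes: List[List[str]] = []
    for g in order:
        if classes and all(same_class(g, m) for m in classes[-1]):
            classes[-1].append(g)
        else:
            classes.append([g])
    return Ranking(classes=classes)


# ---------------------------------------------------------------------------
# input stages


def _load_manifest(manifest: str) -> List[HeightMap]:
    path = Path(manifest)
    table = pd.read_csv(path, dtype=str)
    needed = {"file", "format", "specimen_id", "group_label"}
    if not needed.issubset(table.columns):
        raise ValidationError(
            f"manifest must have columns {sorted(needed)}, got {list(table.columns)}"
        )
    surfaces = []
    for _, row in table.iterrows():
        fp = Path(row["file"])
        if not fp.is_absolute():
            fp = path.parent / fp
        surfaces.append(
            read_height_map(
                fp, row["format"],
                specimen_id=row["specimen_id"], group_label=row["group_label"],
            )
        )
    return surfaces


def _resolve_presets(simulate: dict) -> List[HabitatPreset]:
    presets = simulate.get("presets")
    if presets is None:
        return list(HABITAT_PRESETS.values())
    if isinstance(presets, dict):
        return [
            HabitatPreset(name, float(v["mean_sa"]), float(v["sd_sa"]), int(v["n"]))
            for name, v in presets.items()
        ]
    return [HABITAT_PRESETS[name] for name in presets]


def _simulate_block_surfaces(simulate: dict) -> List[HeightMap]:
    seed = int(simulate.get("seed", 0))
    spec = SurfaceSpec(**simulate.get("spec", {}))
    surfaces: List[HeightMap] = []
    for i, preset in enumerate(_resolve_presets(simulate)):
        group_seed = int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31 - 1)
        )
        surfaces.extend(sample_habitat(preset, group_seed, template=spec))
    return surfaces


def simulate_surfaces(simulate: dict, out_dir) -> Path:
    """Write simulated surfaces as ascii-grid files plus a manifest CSV.

    Returns the manifest path; the manifest can be fed back to
    :func:`run_study` through ``StudyConfig(manifest=...)``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in _simulate_block_surfaces(simulate):
        fname = f"{s.specimen_id}.asc"
        write_height_map(s, out / fname, "ascii-grid")
        rows.append({
            "file": fname, "format": "ascii-grid",
            "specimen_id": s.specimen_id, "group_label": s.group_label,
        })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def compute_parameter_table(
    surfaces: Sequence[HeightMap], level: bool = True, **iso_overrides
) -> pd.DataFrame:
    """Reduce surfaces to one parameter row per specimen."""
    rows = []
    for s in surfaces:
        ps = compute_all(s, level=level, **iso_overrides)
        rec = {"specimen_id": s.specimen_id, "group_label": s.group_label}
        rec.update({k: ps.values[k] for k in PARAM_ORDER})
        rows.append(rec)
    return pd.DataFrame(rows, columns=["specimen_id", "group_label", *PARAM_ORDER])


# ---------------------------------------------------------------------------
# orchestration


def _config_hash(cfg: StudyConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the full study and (optionally) write all report tables.

    Stages: load or simulate surfaces, compute the 30 parameters per
    specimen, descriptive table, omnibus table, pairwise consensus table,
    consensus-significant parameter list, abrasiveness ranking.  With
    ``cfg.out_dir`` set, writes ``parameters.csv``, ``descriptives.csv``,
    ``omnibus.csv``, ``pairwise.csv`` and ``report.json``.  Deterministic
    given the config (including the simulation seed).
    """
    if cfg.manifest is not None:
        surfaces = _load_manifest(cfg.manifest)
    else:
        surfaces = _simulate_block_surfaces(cfg.simulate)

    labels = [s.group_label for s in surfaces]
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValidationError(f"need at least 2 groups, got {len(counts)}")
    if (counts < 1).any() or any(lbl == "" for lbl in labels):
        raise ValidationError("every specimen needs a non-empty group label")

    df = compute_parameter_table(surfaces, level=cfg.level, **cfg.iso_overrides)
    desc = descriptives(df)
    omnibus, pairwise, significant, skipped = compare_parameters(df, cfg.stats)
    if omnibus.empty:
        raise ValidationError(
            "no parameter could be tested: " + "; ".join(skipped.values())
        )
    ranking = rank_abrasiveness(desc, significant, pairwise)

    provenance = {
        "config_hash": _config_hash(cfg),
        "seed": None if cfg.simulate is None else cfg.simulate.get("seed"),
        "n_specimens": len(surfaces),
        "groups": {str(k): int(v) for k, v in counts.sort_index().items()},
        "gamma": cfg.stats.gamma,
        "alpha": cfg.stats.alpha,
    }
    report = StudyReport(
        parameters=df, descriptive=desc, omnibus=omnibus, pairwise=pairwise,
        significant=significant, ranking=ranking, skipped=skipped,
        provenance=provenance,
    )
    if cfg.out_dir is not None:
        _write_report(report, Path(cfg.out_dir))
    return report


def _write_report(report: StudyReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    kw = dict(index=False, float_format="%.12g")
    report.parameters.to_csv(out / "parameters.csv", **kw)
    report.descriptive.to_csv(out / "descriptives.csv", **kw)
    report.omnibus.to_csv(out / "omnibus.csv", **kw)
    report.pairwise.to_csv(out / "pairwise.csv", **kw)
    summary = {
        "provenance": report.provenance,
        "significant_parameters": report.significant,
        "ranking": report.ranking.format(),
        "ranking_classes": report.ranking.classes,
        "skipped_parameters": report.skipped,
        "omnibus": report.omnibus.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
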