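"""End-to-end study driver mirroring the paper-style comparison battery.

For every subject the driver computes all wave-speed variants — catheter
pullback (regional two-site and local trajectory regression), in-plane CMR
(regional and local chord-onset regression), through-plane CMR (two-site) —
plus the local distensibility with both pulse-pressure sources (catheter and
brachial cuff) and the Bramwell-Hill modeled wave speed, then runs the full
agreement battery on each method against the pressure gold standard and the
association table of each wave speed with distensibility^(-1/2).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import (
    AgreementReport,
    CorrelationComparison,
    PairedSeries,
    agreement,
    compare_method_correlations,
)
from .bramwell import BloodConstants, distensibility, theoretical_pwv
from .cohort import Cohort, CohortConfig, SubjectData
from .errors import AortaPWVError, FootDetectionError, SampleSizeError
from .feet import detect_onset_velocity
from .pwv import SiteOnset, multi_site_pwv, pullback_pwv, two_site_pwv
from .waveforms import segment_cycles

__all__ = ["SubjectEstimates", "StudyReport", "analyze_subject", "run_study", "config_hash"]

_PWV_COLUMNS = [
    "pwv_pressure_regional",
    "pwv_pressure_local",
    "pwv_tp_regional",
    "pwv_ip_regional",
    "pwv_ip_local",
    "pwv_bh_cuff",
    "pwv_bh_cath",
]


@dataclass
class SubjectEstimates:
    """All per-subject measurements; NaN marks a failed stage."""

    subject: str
    pwv_pressure_regional: float = float("nan")
    pwv_pressure_local: float = float("nan")
    pwv_tp_regional: float = float("nan")
    pwv_ip_regional: float = float("nan")
    pwv_ip_local: float = float("nan")
    pp_cath_mmHg: float = float("nan")
    pp_cuff_mmHg: float = float("nan")
    delta_A_mm2: float = float("nan")
    A_min_mm2: float = float("nan")
    D_cath_per_Pa: float = float("nan")
    D_cuff_per_Pa: float = float("nan")
    pwv_bh_cuff: float = float("nan")
    pwv_bh_cath: float = float("nan")
    n_chords_excluded: int = 0
    failures: list = field(default_factory=list)


def pulse_pressure_from_recording(recording) -> float:
    """Median over cycles of per-cycle (max - min) pressure, in mmHg."""
    cycles = segment_cycles(recording)
    return float(np.median([np.ptp(c.values) for c in cycles]))


def analyze_subject(
    data: SubjectData,
    *,
    site1_m: float,
    site2_m: float,
    pullback_step_m: float = 0.058,
    constants: BloodConstants = BloodConstants(),
) -> SubjectEstimates:
    """Run every estimator on one subject's data streams."""
    est = SubjectEstimates(subject=data.subject_id)

    def _try(name, fn):
        try:
            return fn()
        except AortaPWVError as exc:
            est.failures.append(f"{name}: {type(exc).__name__}: {exc}")
            return None

    r = _try(
        "pullback_regional",
        lambda: pullback_pwv(
            data.pullback, "regional", site1_m=site1_m, site2_m=site2_m
        ),
    )
    if r:
        est.pwv_pressure_regional = r.pwv_m_per_s
    r = _try(
        "pullback_local", lambda: pullback_pwv(data.pullback, "local", center_m=site2_m)
    )
    if r:
        est.pwv_pressure_local = r.pwv_m_per_s

    # in-plane: chord onsets -> distance-time regression
    sites: list[SiteOnset] = []
    n_failed = 0
    for s, curve in zip(data.chord_positions_m, data.chord_curves):
        try:
            sites.append(SiteOnset(float(s), detect_onset_velocity(curve)))
        except FootDetectionError:
            n_failed += 1
    est.n_chords_excluded = n_failed
    tol = 1e-9
    r = _try(
        "ip_regional",
        lambda: multi_site_pwv(sites, (site1_m - tol, site2_m + tol)),
    )
    if r:
        est.pwv_ip_regional = r.pwv_m_per_s
    r = _try(
        "ip_local",
        lambda: multi_site_pwv(
            sites, (site2_m - pullback_step_m - tol, site2_m + pullback_step_m + tol)
        ),
    )
    if r:
        est.pwv_ip_local = r.pwv_m_per_s

    # through-plane: two-site on the ROI maximal-velocity curves
    def _tp():
        o1 = SiteOnset(data.tp_positions_m[0], detect_onset_velocity(data.tp_curves[0]))
        o2 = SiteOnset(data.tp_positions_m[1], detect_onset_velocity(data.tp_curves[1]))
        return two_site_pwv(o1, o2)

    r = _try("tp_regional", _tp)
    if r:
        est.pwv_tp_regional = r.pwv_m_per_s

    # local pulse pressures and distensibility at site 2
    def _pp_cath():
        positions = np.array([rec.site_position_m for rec in data.pullback])
        i = int(np.argmin(np.abs(positions - site2_m)))
        return pulse_pressure_from_recording(data.pullback[i])

    pp_cath = _try("pp_cath", _pp_cath)
    if pp_cath:
        est.pp_cath_mmHg = pp_cath
    est.pp_cuff_mmHg = data.cuff_pp_mmHg

    areas = data.area_curve.values
    est.delta_A_mm2 = float(areas.max() - areas.min())
    est.A_min_mm2 = float(areas.min())

    for tag, pp in (("cath", est.pp_cath_mmHg), ("cuff", est.pp_cuff_mmHg)):
        def _bh(pp=pp):
            d = distensibility(est.delta_A_mm2, est.A_min_mm2, pp)
            return d.D_per_Pa, theoretical_pwv(d, constants)

        res = _try(f"bh_{tag}", _bh)
        if res:
            if tag == "cath":
                est.D_cath_per_Pa, est.pwv_bh_cath = res
            else:
                est.D_cuff_per_Pa, est.pwv_bh_cuff = res
    return est


@dataclass
class StudyReport:
    """Per-method tables, agreement battery and association table."""

    per_subject: pd.DataFrame
    agreements: dict[str, AgreementReport]
    correlation_contrasts: dict[str, CorrelationComparison]
    association: pd.DataFrame
    n_subjects: int
    n_used: int
    excluded_subjects: dict[str, list]
    seed: int | None = None
    config_hash: str | None = None

    def to_dict(self) -> dict:
        return {
            "meta": {
                "seed": self.seed,
                "config_hash": self.config_hash,
                "n_subjects": self.n_subjects,
                "n_used": self.n_used,
                "excluded_subjects": self.excluded_subjects,
            },
            "per_subject": self.per_subject.to_dict(orient="records"),
            "agreements": {k: v.to_dict() for k, v in self.agreements.items()},
            "correlation_contrasts": {
                k: {
                    "p_value": v.p_value,
                    "interaction_coef": v.interaction_coef,
                    "coefs": v.coefs,
                }
                for k, v in self.correlation_contrasts.items()
            },
            "association": self.association.to_dict(orient="records"),
        }

    def write(self, out_dir: str | Path, *, plots: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.per_subject.to_csv(out / "per_subject.csv", index=False)
        pd.DataFrame(
            [{"comparison": k, **v.to_dict()} for k, v in self.agreements.items()]
        ).to_csv(out / "agreement.csv", index=False)
        self.association.to_csv(out / "association.csv", index=False)
        if plots:
            self._plot(out / "plots")

    def _plot(self, plot_dir: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plot_dir.mkdir(parents=True, exist_ok=True)
        for name, rep in self.agreements.items():
            test_col, ref_col = _COMPARISONS[name]
            sub = self.per_subject.dropna(subset=[test_col, ref_col])
            t, r = sub[test_col], sub[ref_col]
            fig, axes = plt.subplots(1, 2, figsize=(9, 4))
            axes[0].scatter(r, t, s=18)
            lim = [min(r.min(), t.min()) - 0.5, max(r.max(), t.max()) + 0.5]
            axes[0].plot(lim, lim, "k--", lw=0.8)
            axes[0].set_xlabel(ref_col)
            axes[0].set_ylabel(test_col)
            axes[0].set_title(f"r = {rep.pearson_r:.2f}")
            mean_both = (t + r) / 2
            axes[1].scatter(mean_both, t - r, s=18)
            for y in (rep.mean_diff, rep.loa_lo, rep.loa_hi):
                axes[1].axhline(y, color="k", ls="--", lw=0.8)
            axes[1].set_xlabel("mean of methods (m/s)")
            axes[1].set_ylabel("difference (m/s)")
            axes[1].set_title("Bland-Altman")
            fig.tight_layout()
            fig.savefig(plot_dir / f"{name}.png", dpi=110)
            plt.close(fig)


#: comparison name -> (method-under-test column, reference column)
_COMPARISONS = {
    "tp_regional_vs_pressure_regional": ("pwv_tp_regional", "pwv_pressure_regional"),
    "ip_regional_vs_pressure_regional": ("pwv_ip_regional", "pwv_pressure_regional"),
    "ip_local_vs_pressure_local": ("pwv_ip_local", "pwv_pressure_local"),
    "bh_cuff_vs_pressure_local": ("pwv_bh_cuff", "pwv_pressure_local"),
    "bh_cath_vs_pressure_local": ("pwv_bh_cath", "pwv_pressure_local"),
}


def config_hash(config: CohortConfig) -> str:
    payload = json.dumps(
        {k: (v if not hasattr(v, "__dict__") else vars(v)) for k, v in vars(config).items()},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_study(
    subjects: Sequence[SubjectData] | Cohort,
    *,
    site1_m: float | None = None,
    site2_m: float | None = None,
    pullback_step_m: float = 0.058,
    constants: BloodConstants = BloodConstants(),
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> StudyReport:
    """Compute every estimator and the full comparison battery for a study.

    Subjects with any failed stage are excluded listwise from the paired
    statistics (the per-subject table keeps their partial results); at least
    3 complete subjects are required.
    """
    if isinstance(subjects, Cohort):
        cfg = subjects.config
        site1_m = cfg.site1_m if site1_m is None else site1_m
        site2_m = cfg.site2_m if site2_m is None else site2_m
        pullback_step_m = cfg.pullback_step_m
        seed = cfg.seed if seed is None else seed
        cfg_hash = config_hash(cfg) if cfg_hash is None else cfg_hash
        subject_list = list(subjects.subjects)
    else:
        subject_list = list(subjects)
        if site1_m is None or site2_m is None:
            raise ValueError("site1_m and site2_m are required")
    if len(subject_list) < 3:
        raise SampleSizeError("need >= 3 subjects for the study battery")

    estimates = [
        analyze_subject(
            s,
            site1_m=site1_m,
            site2_m=site2_m,
            pullback_step_m=pullback_step_m,
            constants=constants,
        )
        for s in subject_list
    ]
    rows = []
    for e in estimates:
        row = {k: v for k, v in vars(e).items() if k != "failures"}
        rows.append(row)
    table = pd.DataFrame(rows)

    complete = table.dropna(subset=_PWV_COLUMNS)
    excluded = {
        e.subject: e.failures
        for e in estimates
        if e.subject not in set(complete["subject"])
    }
    if len(complete) < 3:
        raise SampleSizeError(
            f"only {len(complete)} subjects with all stages complete"
        )

    labels = tuple(complete["subject"])

    def _series(test_col, ref_col):
        return PairedSeries(
            complete[test_col].to_numpy(), complete[ref_col].to_numpy(), labels
        )

    agreements = {
        name: agreement(_series(t_col, r_col))
        for name, (t_col, r_col) in _COMPARISONS.items()
    }
    contrasts = {
        "ip_vs_tp_regional": compare_method_correlations(
            _series("pwv_ip_regional", "pwv_pressure_regional"),
            _series("pwv_tp_regional", "pwv_pressure_regional"),
        ),
        "bh_cuff_vs_bh_cath": compare_method_correlations(
            _series("pwv_bh_cuff", "pwv_pressure_local"),
            _series("pwv_bh_cath", "pwv_pressure_local"),
        ),
    }

    # association of each wave speed with distensibility^(-1/2)
    import scipy.stats as st

    assoc_rows = []
    for pwv_col in [
        "pwv_tp_regional",
        "pwv_ip_regional",
        "pwv_ip_local",
        "pwv_pressure_regional",
        "pwv_pressure_local",
    ]:
        for src, d_col in (("cuff", "D_cuff_per_Pa"), ("cath", "D_cath_per_Pa")):
            x = complete[d_col].to_numpy() ** -0.5
            y = complete[pwv_col].to_numpy()
            res = st.pearsonr(y, x)
            assoc_rows.append(
                {
                    "pwv_method": pwv_col,
                    "pp_source": src,
                    "r": float(res.statistic),
                    "p": float(res.pvalue),
                    "n": len(complete),
                }
            )
    association = pd.DataFrame(assoc_rows)

    return StudyReport(
        per_subject=table,
        agreements=agreements,
        correlation_contrasts=contrasts,
        association=association,
        n_subjects=len(subject_list),
        n_used=len(complete),
        excluded_subjects=excluded,
        seed=seed,
        config_hash=cfg_hash,
    )
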