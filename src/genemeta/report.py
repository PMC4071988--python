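"""Report rendering and reproduction checks.

JSON output carries unrounded values; TSV/markdown round odds ratios and
interval bounds half-up to 2 decimals, the convention of the published
association tables the bundled datasets come from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

from .bias import begg_test, egger_test
from .pooling import MetaAnalysisResult, leave_one_out, meta_analyze
from .types import GeneticModel, MetaConfig, SNPDataset

log = logging.getLogger("genemeta")

__all__ = [
    "round_half_up",
    "build_report",
    "render",
    "compare_with_published",
    "load_reference_estimates",
    "CellDeviation",
    "ComparisonReport",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (2.005 -> 2.01), as legacy tables were printed."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(float(x))).quantize(exp, rounding=ROUND_HALF_UP))


def _effect_dict(e) -> dict:
    return {
        "or": e.or_,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "log_or": e.log_or,
        "se": e.se,
        "p": e.p_value,
        "corrected": e.corrected,
    }


def build_report(ds: SNPDataset, cfg: MetaConfig | None = None) -> dict:
    """Run the full pipeline on a dataset and assemble a report bundle.

    Contains per-study rows (counts, HWE, one OR cell per genetic model),
    pooled and heterogeneity blocks per model, leave-one-out sensitivity and
    publication-bias diagnostics when k >= 3, and quality scores when study
    metadata is present.  All values unrounded.
    """
    cfg = cfg or MetaConfig()
    res: MetaAnalysisResult = meta_analyze(ds, cfg)
    log.info(
        "analyzed %s: k=%d, methods=%s",
        ds.snp_id,
        ds.k,
        {m.value: res.pooled[m].method.value for m in GeneticModel},
    )
    bundle: dict = {
        "snp_id": ds.snp_id,
        "k": ds.k,
        "config": {
            "heterogeneity_alpha": cfg.heterogeneity_alpha,
            "fixed_method": cfg.fixed_method.value,
            "cc": cfg.cc.value,
            "hwe_alpha": cfg.hwe_alpha,
        },
        "studies": [],
        "pooled": {},
        "sensitivity": {},
        "bias": {},
        "quality": {},
    }
    for i, s in enumerate(ds.studies):
        hwe = res.hwe[s.study_id]
        bundle["studies"].append(
            {
                "study_id": s.study_id,
                "year": s.year,
                "cases": [s.cases.n11, s.cases.n12, s.cases.n22],
                "controls": [s.controls.n11, s.controls.n12, s.controls.n22],
                "hwe": {
                    "chi_square": hwe.chi_square,
                    "p": hwe.p_value,
                    "in_equilibrium": hwe.in_equilibrium,
                },
                "effects": {
                    m.value: _effect_dict(res.effects[m][i]) for m in GeneticModel
                },
            }
        )
    for m in GeneticModel:
        pooled = res.pooled[m]
        het = pooled.heterogeneity
        bundle["pooled"][m.value] = {
            "method": pooled.method.value,
            "estimate": _effect_dict(pooled.estimate),
            "heterogeneity": {
                "q": het.q,
                "df": het.df,
                "p": het.p_value,
                "i_squared": het.i_squared,
                "tau_squared": het.tau_squared,
            },
            "k": pooled.k,
        }
    if ds.k >= 3:
        for m in GeneticModel:
            bundle["sensitivity"][m.value] = [
                {"omitted": r.omitted_study_id, "estimate": _effect_dict(r.estimate)}
                for r in leave_one_out(ds, m, cfg)
            ]
            effects = res.effects[m]
            egger = egger_test(effects)
            begg = begg_test(effects)
            bundle["bias"][m.value] = {
                "egger": {
                    "intercept": egger.intercept,
                    "se_intercept": egger.se_intercept,
                    "t": egger.t_statistic,
                    "df": egger.df,
                    "p": egger.p_value,
                    "slope": egger.slope,
                },
                "begg": {"kendall_tau": begg.kendall_tau, "p": begg.p_value, "exact": begg.exact},
            }
    else:
        note = f"not estimable with k={ds.k} (< 3 studies)"
        bundle["sensitivity"] = {"note": note}
        bundle["bias"] = {"note": note}
    for sid, q in res.quality.items():
        bundle["quality"][sid] = {
            "total": q.total,
            "per_category": dict(q.per_category),
            "is_high_quality": q.is_high_quality,
        }
    return bundle


def _fmt_cell(eff: dict) -> str:
    return (
        f"{round_half_up(eff['or']):.2f} "
        f"[{round_half_up(eff['ci_low']):.2f}, {round_half_up(eff['ci_high']):.2f}] "
        f"p={eff['p']:.3g}"
    )


def _render_rows(bundle: dict) -> tuple[list[str], list[list[str]]]:
    models = [m.value for m in GeneticModel]
    header = ["study_id", "year", "cases(11/12/22)", "controls(11/12/22)", "HWE"] + models
    rows = []
    for s in bundle["studies"]:
        rows.append(
            [
                s["study_id"],
                str(s["year"]),
                "/".join(map(str, s["cases"])),
                "/".join(map(str, s["controls"])),
                "Yes" if s["hwe"]["in_equilibrium"] else "No",
            ]
            + [_fmt_cell(s["effects"][m]) for m in models]
        )
    total = ["Total", "", str(bundle["k"]) + " studies", "", ""]
    het = ["Heterogeneity", "", "", "", ""]
    for m in models:
        p = bundle["pooled"][m]
        total.append(_fmt_cell(p["estimate"]) + f" ({p['method']})")
        het.append(f"Q={p['heterogeneity']['q']:.2f} p={p['heterogeneity']['p']:.2f}")
    rows.extend([total, het])
    return header, rows


def render(bundle: dict, fmt: str = "markdown") -> str:
    """Serialise a report bundle as json (unrounded), tsv or markdown."""
    if fmt == "json":
        return json.dumps(bundle, indent=2)
    header, rows = _render_rows(bundle)
    if fmt == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
        return "\n".join(lines)
    if fmt == "markdown":
        lines = [
            f"## {bundle['snp_id']} (k={bundle['k']})",
            "",
            "| " + " | ".join(header) + " |",
            "|" + "|".join(["---"] * len(header)) + "|",
        ]
        lines += ["| " + " | ".join(r) + " |" for r in rows]
        if bundle["quality"]:
            lines += ["", "Quality scores: " + ", ".join(
                f"{sid}={q['total']}" for sid, q in bundle["quality"].items()
            )]
        if isinstance(bundle["bias"], dict) and "note" in bundle["bias"]:
            lines += ["", f"Sensitivity / bias diagnostics: {bundle['bias']['note']}"]
        elif bundle["bias"]:
            lines += ["", "Egger's test p-values: " + ", ".join(
                f"{m}={d['egger']['p']:.2f}" for m, d in bundle["bias"].items()
            )]
        return "\n".join(lines)
    raise ValueError(f"unknown format {fmt!r}; expected json, tsv or markdown")


def load_reference_estimates() -> dict:
    """The bundled published OR/CI cells (2-decimal) for the three SNPs."""
    ref = resources.files("genemeta.data").joinpath("reference_estimates.json")
    data = json.loads(ref.read_text(encoding="utf-8"))
    data.pop("_comment", None)
    return data


@dataclass(frozen=True)
class CellDeviation:
    snp_id: str
    study_id: str  # "pooled" for the total row
    model: str
    quantity: str  # "or", "ci_low" or "ci_high"
    computed: float  # rounded half-up to 2 decimals
    published: float

    @property
    def deviation(self) -> float:
        return abs(self.computed - self.published)


@dataclass(frozen=True)
class ComparisonReport:
    deviations: list[CellDeviation]

    @property
    def max_deviation(self) -> float:
        return max(d.deviation for d in self.deviations)

    @property
    def n_cells(self) -> int:
        return len(self.deviations)

    def within(self, tol: float = 0.01) -> bool:
        return self.max_deviation <= tol + 1e-12


def compare_with_published(
    datasets: dict[str, SNPDataset] | None = None,
    cfg: MetaConfig | None = None,
) -> ComparisonReport:
    """Recompute every per-study and pooled OR/CI cell and diff it against
    the published 2-decimal values.

    ``datasets`` overrides the bundled tables (used to show the diff is
    sensitive to tampered counts); by default the bundled data are used.
    """
    from .io import load_fixture

    reference = load_reference_estimates()
    cfg = cfg or MetaConfig()
    devs: list[CellDeviation] = []
    for snp_id, ref in reference.items():
        ds = (datasets or {}).get(snp_id) or load_fixture(snp_id)
        res = meta_analyze(ds, cfg)
        idx = {sid: i for i, sid in enumerate(res.study_ids)}
        for sid, cells in ref["per_study"].items():
            for model, (or_ref, lo_ref, hi_ref) in cells.items():
                e = res.effects[GeneticModel(model)][idx[sid]]
                for qty, comp, pub in (
                    ("or", e.or_, or_ref),
                    ("ci_low", e.ci_low, lo_ref),
                    ("ci_high", e.ci_high, hi_ref),
                ):
                    devs.append(
                        CellDeviation(snp_id, sid, model, qty, round_half_up(comp), pub)
                    )
        for model, (or_ref, lo_ref, hi_ref) in ref["pooled"].items():
            e = res.pooled[GeneticModel(model)].estimate
            for qty, comp, pub in (
                ("or", e.or_, or_ref),
                ("ci_low", e.ci_low, lo_ref),
                ("ci_high", e.ci_high, hi_ref),
            ):
                devs.append(
                    CellDeviation(snp_id, "pooled", model, qty, round_half_up(comp), pub)
                )
    return ComparisonReport(devs)
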