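"""Pipeline drivers: X-dimer compatibility analysis and mutant design screen.

`run_xdimer_compatibility` asks, for each candidate dimer template, whether
two copies of the antibody–antigen complex can decorate the dimer
simultaneously: it builds the hypothetical assembly, measures the vdW
overlap volume between the two placed antibody bodies, and issues a
clash / no-clash verdict.  `run_design_screen` ranks candidate antibody
point mutations by how much they shift the signed clearance between the
two antibody copies on a given template — the score used to engineer a
clash into an otherwise compatible dimer.

Every report records all parameters (selections, grid spacing, radii
provenance, probe) so the analysis can be re-run bit-identically from the
report alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .assembly import build_hypothetical_assembly, mutate_residue
from .errors import XdcError
from .sterics import (
    DEFAULT_GRID_SPACING,
    DEFAULT_PROBE_RADIUS,
    Body,
    overlap_volume,
    signed_clearance,
)
from .structure import Selection, Structure, resolve_selection

SCHEMA_VERSION = "1"


@dataclass
class PipelineConfig:
    """Selections and numerical parameters shared by the pipeline stages."""

    antigen: str  # selection string on the complex, e.g. "G:10-99"
    protomerA: str  # selection string on the template
    protomerB: str
    antibody: str  # chains of the antibody body in the complex, e.g. "H,L"
    grid_spacing: float = DEFAULT_GRID_SPACING
    probe: float = DEFAULT_PROBE_RADIUS
    clash_floor: float = 0.0  # ų; clash verdict iff volume > floor
    radii_table: str = "builtin"

    def selections(self) -> dict[str, Selection]:
        return {
            "antigen": Selection.parse(self.antigen),
            "protomerA": Selection.parse(self.protomerA),
            "protomerB": Selection.parse(self.protomerB),
            "antibody": Selection.parse(self.antibody),
        }


@dataclass
class AnalysisReport:
    """Structured, self-sufficient record of one pipeline run."""

    analysis: str
    schema_version: str = SCHEMA_VERSION
    inputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    verdicts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _antibody_body(placed: Structure, antibody_sel: Selection) -> Body:
    return Body.from_atoms(resolve_selection(placed, antibody_sel))


def run_xdimer_compatibility(
    complex_structure: Structure,
    templates: dict[str, Structure],
    config: PipelineConfig,
) -> AnalysisReport:
    """Overlap volume + clash verdict of the antibody pair per dimer template."""
    if not templates:
        raise XdcError("no templates given")
    sels = config.selections()
    report = AnalysisReport(
        analysis="xdimer_compatibility",
        inputs={
            "complex": complex_structure.entry_id,
            "templates": sorted(templates),
        },
        parameters=asdict(config),
    )
    for name, template in templates.items():
        t0 = time.perf_counter()
        try:
            model = build_hypothetical_assembly(
                complex_structure,
                template,
                sels["protomerA"],
                sels["protomerB"],
                sels["antigen"],
            )
            pairA = _antibody_body(model.copyA, sels["antibody"])
            pairB = _antibody_body(model.copyB, sels["antibody"])
            result = overlap_volume(pairA, pairB, config.grid_spacing)
        except XdcError as exc:
            raise XdcError(f"[template {name}] {exc}") from exc
        report.results[name] = {
            "overlap_volume_A3": result.volume,
            "n_clash_pairs": len(result.clash_pairs),
            "worst_clash_pairs": result.clash_pairs[:10],
            "fit_rmsds_A": list(model.fit_rmsds),
            "grid_spacing_A": result.grid_spacing,
        }
        report.verdicts[name] = (
            "clash" if result.volume > config.clash_floor else "no-clash"
        )
        report.timings_s[name] = round(time.perf_counter() - t0, 3)
    return report


def run_design_screen(
    complex_structure: Structure,
    template: Structure,
    mutations: list[tuple[str, int, str]],
    config: PipelineConfig,
) -> AnalysisReport:
    """Signed clearance before/after each candidate mutation, Δ-ranked.

    ``mutations`` entries are (chain, resseq, new_residue) on the complex;
    the mutation lands in both placed copies because they are rigid
    transforms of the same mutated complex.  The signed-clearance scale is
    method-divergent from molecular-surface programs (see sterics module);
    its sign and ordering are the designed-for signal.
    """
    sels = config.selections()

    def score(c: Structure):
        model = build_hypothetical_assembly(
            c, template, sels["protomerA"], sels["protomerB"], sels["antigen"]
        )
        res = signed_clearance(
            _antibody_body(model.copyA, sels["antibody"]),
            _antibody_body(model.copyB, sels["antibody"]),
            config.grid_spacing,
            config.probe,
        )
        return res

    t0 = time.perf_counter()
    base = score(complex_structure)
    report = AnalysisReport(
        analysis="design_screen",
        inputs={"complex": complex_structure.entry_id, "template": template.entry_id},
        parameters={
            **asdict(config),
            "mutations": [f"{c}:{r}->{n}" for c, r, n in mutations],
            "score_note": "negative branch is probe-inflated overlap, method-divergent",
        },
    )
    report.results["wild_type"] = {
        "signed_score_A3": base.signed_score,
        "far_apart": base.far_apart,
    }
    for chain, resseq, new_res in mutations:
        mutated = mutate_residue(complex_structure, chain, resseq, new_res)
        res = score(mutated)
        delta = res.signed_score - base.signed_score
        key = f"{chain}:{resseq}->{new_res.upper()}"
        report.results[key] = {
            "signed_score_A3": res.signed_score,
            "delta_A3": delta,
            "far_apart": res.far_apart,
            "flips_to_clash": base.signed_score <= 0.0 < res.signed_score,
        }
        report.verdicts[key] = "clash" if res.signed_score > 0 else "no-clash"
    ranked = sorted(
        (k for k in report.results if k != "wild_type"),
        key=lambda k: -report.results[k]["delta_A3"],
    )
    report.results["ranking"] = ranked
    report.verdicts["wild_type"] = "clash" if base.signed_score > 0 else "no-clash"
    report.timings_s["total"] = round(time.perf_counter() - t0, 3)
    return report
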