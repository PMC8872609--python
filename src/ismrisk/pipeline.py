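"""End-to-end orchestration: selection → ISM → MICMAC with one report.

A run consumes a register, one degree source (a precomputed degree table
or an adjacency matrix), and optionally an SSIM over the selected key
risks; it produces a single :class:`RunReport` holding every
intermediate artifact plus the warnings collected along the way. Runs
are deterministic: identical inputs give byte-identical serialized
reports.
"""

from __future__ import annotations

import json
import logging
import warnings as _warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import ism, network
from .micmac import QUADRANTS, MicmacResult, micmac as _compute_micmac
from .errors import ElementMismatchWarning, IsmRiskError, IsmRiskWarning, ValidationError
from .register import RiskRegister, code_sort_key, parse_register

log = logging.getLogger("ismrisk")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of ``degrees``/``adjacency`` must be given; ``ssim`` is
    optional (without it the run stops after selection). Selection uses
    ``threshold`` if set, else the upper ``quantile``.
    """

    register: str | Path | None = None
    degrees: str | Path | None = None
    adjacency: str | Path | None = None
    ssim: str | Path | None = None
    threshold: float | None = None
    quantile: float | None = None
    quantile_method: str = "linear"
    midpoint: float | str = "auto"
    outdir: str | Path | None = None
    strict: bool = False
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if (self.degrees is None) == (self.adjacency is None):
            raise ValidationError("provide exactly one of degrees / adjacency")
        if self.threshold is None and self.quantile is None:
            raise ValidationError("provide a threshold or a quantile for selection")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat ``key = value`` config file; keyword overrides win."""
        raw: dict[str, str] = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            if "=" not in ln:
                raise ValidationError(f"config line is not key = value: {ln!r}")
            k, v = ln.split("=", 1)
            raw[k.strip()] = v.strip()
        kwargs: dict = {}
        for k, v in raw.items():
            if k in ("threshold", "quantile"):
                kwargs[k] = float(v)
            elif k == "midpoint":
                kwargs[k] = v if v == "auto" else float(v)
            elif k == "strict":
                kwargs[k] = v.lower() in ("1", "true", "yes")
            elif k == "seed":
                kwargs[k] = int(v)
            else:
                kwargs[k] = v
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def selection_rule(self) -> network.SelectionRule:
        if self.threshold is not None:
            return network.SelectionRule.explicit(self.threshold)
        return network.SelectionRule.upper_quantile(self.quantile, self.quantile_method)  # type: ignore[arg-type]


@dataclass
class RunReport:
    """Everything one run produced, in one serializable object."""

    register: RiskRegister | None
    centrality: network.CentralityTable
    selection_cutoff: float
    selected: list[str]
    ssim: ism.SSIM | None = None
    initial: ism.ReachabilityMatrix | None = None
    final: ism.ReachabilityMatrix | None = None
    partition: ism.LevelPartition | None = None
    hierarchy: ism.HierarchyDigraph | None = None
    micmac: MicmacResult | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {
            "selection": {
                "cutoff": self.selection_cutoff,
                "selected": self.selected,
                "scores": {c: self.centrality[c] for c in self.selected},
            },
            "warnings": self.warnings,
        }
        if self.register is not None:
            out["register"] = {"n_risks": len(self.register), "segments": list(self.register.segments)}
        if self.final is not None and self.initial is not None:
            order = list(self.final.elements)
            out["ism"] = {
                "elements": order,
                "initial": self.initial.to_frame().values.tolist(),
                "final": self.final.to_frame().values.tolist(),
                "derived": self.final.derived_frame().values.tolist(),
            }
        if self.partition is not None:
            out["levels"] = {
                "by_level": self.partition.as_lists(),
                "depth": self.partition.depth_levels(),
                "audit": [
                    {
                        "code": r.code,
                        "level": r.level,
                        "reachability": sorted(r.reachability, key=code_sort_key),
                        "antecedent": sorted(r.antecedent, key=code_sort_key),
                        "intersection": sorted(r.intersection, key=code_sort_key),
                    }
                    for r in self.partition.audit
                ],
            }
        if self.hierarchy is not None:
            out["hierarchy"] = json.loads(self.hierarchy.to_json())
        if self.micmac is not None:
            out["micmac"] = json.loads(self.micmac.summary_json())
            out["micmac"]["powers"] = {
                c: [self.micmac.powers.driving[c], self.micmac.powers.dependence[c]]
                for c in self.micmac.elements
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary_text(self) -> str:
        lines = [f"key risks ({len(self.selected)}; cutoff {self.selection_cutoff:g}):"]
        lines.append("  " + ", ".join(self.selected))
        if self.partition is not None:
            for k, members in enumerate(self.partition.as_lists(), start=1):
                lines.append(f"level {k}: {', '.join(members)}")
        if self.micmac is not None:
            for q in QUADRANTS:
                mem = self.micmac.members(q)
                lines.append(f"{q}: {', '.join(mem) if mem else '(none)'}")
        if self.warnings:
            lines.append(f"warnings: {len(self.warnings)}")
            lines.extend(f"  - {w}" for w in self.warnings)
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n", encoding="utf-8")
        (out / "summary.txt").write_text(self.summary_text(), encoding="utf-8")
        if self.initial is not None and self.final is not None:
            self.initial.to_csv(out / "initial_reachability.csv")
            self.final.to_csv(out / "final_reachability.csv", flags_dest=out / "derived_flags.csv")
        if self.hierarchy is not None:
            self.hierarchy.to_dot(out / "hierarchy.dot")
            self.hierarchy.to_graphml(out / "hierarchy.graphml")
        if self.micmac is not None:
            self.micmac.to_csv(out / "micmac.csv")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute selection, and — when an SSIM is supplied — ISM and MICMAC.

    Warnings (glyph substitutions, element-set mismatches, closure
    corrections) are collected into the report; under ``strict`` they
    become errors.
    """
    logging.basicConfig(level=getattr(logging, str(config.log_level).upper(), logging.WARNING))
    collected: list[str] = []
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always", IsmRiskWarning)
        register = parse_register(config.register) if config.register else None
        if config.degrees is not None:
            table = network.load_centrality(config.degrees)
        else:
            net = network.build_network(network.load_adjacency(config.adjacency))
            table = network.degree_centrality(net)
        rule = config.selection_rule()
        cutoff = rule.cutoff(table.scores.values())
        selected = network.select_key_risks(table, rule)
        log.info("selected %d key risks at cutoff %g", len(selected), cutoff)

        report = RunReport(register, table, cutoff, selected)
        if config.ssim is not None:
            ssim = ism.parse_ssim(config.ssim)
            if set(ssim.elements) != set(selected):
                _warnings.warn(
                    "SSIM element set differs from the selected key risks; "
                    "proceeding on the SSIM elements",
                    ElementMismatchWarning,
                    stacklevel=1,
                )
            initial = ism.ssim_to_initial(ssim)
            final = ism.transitive_closure(initial)
            partition = ism.level_partition(final)
            hierarchy = ism.build_hierarchy(final, partition)
            result = _compute_micmac(final, config.midpoint)
            report = replace(
                report,
                ssim=ssim,
                initial=initial,
                final=final,
                partition=partition,
                hierarchy=hierarchy,
                micmac=result,
            )
        for w in caught:
            if issubclass(w.category, IsmRiskWarning):
                collected.append(str(w.message))
    if config.strict and collected:
        raise IsmRiskError("strict mode: " + "; ".join(collected))
    report.warnings = collected
    if config.outdir is not None:
        report.write(config.outdir)
    return report
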