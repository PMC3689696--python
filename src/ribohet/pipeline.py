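"""End-to-end orchestration: profile -> structure -> trees -> Phi -> report.

The canonical entry points are :func:`run_all` for arbitrary inputs and
:func:`fixture_report` for the bundled study fixture (the 18 cloned
*Metschnikowia* D1/D2 repeats reconstructed from the published
variable-site catalog).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

from . import fixture as fx
from .alphabet import GAP, canon
from .phylo import bootstrap_support, distance_matrix, neighbor_joining, write_newick
from .recomb import phi_permutation_test
from .seqio import Alignment, SequenceRecord, read_clustal, read_fasta, align_center_star
from .structure import (
    EffectClass,
    PairTable,
    SiteRole,
    VR1_DIAGNOSTIC,
    VR2_DIAGNOSTIC_3P,
    VR2_DIAGNOSTIC_5P,
    assign_compensatory_type,
    classify_structural_effect,
    map_site_context,
    pairing_integrity,
)
from .variation import (
    VariableRegion,
    Verdict,
    check_ambiguity_consistency,
    detect_variable_regions,
    pairwise_differences,
    profile_variable_sites,
    substitution_spectrum,
)

__all__ = ["RunConfig", "run_all", "fixture_report"]


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for a full analysis run."""

    alignment: Alignment
    grouping: Mapping[str, str]  # clone id -> group
    consensus_ids: tuple[str, ...] = ()
    pair_tables: tuple[PairTable, ...] = ()
    vr_windows: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    vr_max_gap: int = 5
    vr_min_sites: int = 3
    distance_model: str = "f84"
    bootstrap_replicates: int = 100
    phi_window: int = 100
    phi_permutations: int = 1000
    seed: int | None = None
    outgroup: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None and (self.bootstrap_replicates or self.phi_permutations):
            raise ValueError("stochastic stages enabled but no seed given")


def _clone_alignment(aln: Alignment, grouping: Mapping[str, str]) -> Alignment:
    recs = tuple(r for r in aln.records if r.id in grouping)
    return Alignment(records=recs, offset=aln.offset)


def _spectrum_dict(sp) -> dict:
    return {
        "group": sp.group,
        "n_variable_sites": sp.n_variable_sites,
        "n_transition_sites": sp.n_transition_sites,
        "n_transversion_sites": sp.n_transversion_sites,
        "n_multistate_sites": sp.n_multistate_sites,
        "n_indel_sites": sp.n_indel_sites,
        "n_tc_transition_sites": sp.n_tc_transition_sites,
        "pct_transitions": sp.pct_transitions,
        "pct_tc_among_transitions": sp.pct_tc_among_transitions,
        "pct_transitions_exact": (
            None if sp.pct_transitions_exact is None else str(sp.pct_transitions_exact)
        ),
        "pct_tc_among_transitions_exact": (
            None
            if sp.pct_tc_among_transitions_exact is None
            else str(sp.pct_tc_among_transitions_exact)
        ),
    }


def run_all(config: RunConfig) -> dict:
    """Execute every stage; any stage error aborts naming the stage."""
    report: dict = {"seed": config.seed}
    aln = config.alignment
    grouping = dict(config.grouping)
    clone_aln = _clone_alignment(aln, grouping)

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # --- variable sites and spectra
    sites = stage("profile")(profile_variable_sites, aln, grouping)
    groups = sorted(set(grouping.values()))
    report["n_variable_sites"] = len(sites)
    report["variable_positions"] = [s.position for s in sites]
    report["spectra"] = {
        g: _spectrum_dict(stage("spectrum")(substitution_spectrum, sites, g))
        for g in groups
    }

    # --- variable regions: canonical fixed windows + detected (supplementary)
    regions: dict[str, dict] = {}
    for label, (start, end) in config.vr_windows.items():
        members = tuple(p for p in (s.position for s in sites) if start <= p <= end)
        regions[label] = {
            "start": start, "end": end, "n_sites": len(members), "members": members,
        }
    detected = stage("regions")(
        detect_variable_regions, sites, config.vr_max_gap, config.vr_min_sites
    )
    report["regions"] = {
        "canonical": regions,
        "detected": [
            {"label": r.label, "start": r.start, "end": r.end, "n_sites": len(r)}
            for r in detected
        ],
    }

    # --- ambiguity reconciliation of database consensus rows
    amb: dict[str, dict] = {}
    for rid in config.consensus_ids:
        rec = aln[rid]
        checks = stage("ambiguity")(
            check_ambiguity_consistency, rec, sites, aln, grouping,
            fx.CONSENSUS_GROUPS.get(rid),
        )
        ambiguous = [c for c in checks if len(c.expansion) > 1]
        amb[rid] = {
            "n_ambiguous_symbols": len(ambiguous),
            "n_consistent": sum(1 for c in ambiguous if c.verdict is Verdict.consistent),
            "n_inconsistent": sum(
                1 for c in ambiguous if c.verdict is Verdict.inconsistent
            ),
            "checks": [
                {
                    "position": c.position, "symbol": c.symbol,
                    "observed": "".join(sorted(c.observed)), "verdict": c.verdict.value,
                }
                for c in checks
            ],
        }
    report["ambiguity"] = amb

    # --- structure: site context + effects within the folded windows
    effects: dict[int, str] = {}
    for pt in config.pair_tables:
        in_window = [
            s for s in sites
            if pt.offset <= s.position <= pt.offset + len(pt) - 1
        ]
        ctxs = stage("structure")(map_site_context, pt, in_window, clone_aln)
        for s, ctx in zip(in_window, ctxs):
            joint = None
            if ctx.partner_position is not None:
                c1 = clone_aln.column_of_position(s.position)
                c2 = clone_aln.column_of_position(ctx.partner_position)
                joint = {
                    (canon(r.seq[c1 - 1]), canon(r.seq[c2 - 1]))
                    for r in clone_aln.records
                }
            eff = stage("structure")(classify_structural_effect, s, ctx, joint)
            effects[s.position] = eff.effect.value
    report["structure_effects"] = effects

    # --- compensatory typing at the diagnostic positions
    comp: dict[str, dict] = {}
    have = set(p for s in sites for p in [s.position])
    diag_needed = set(VR1_DIAGNOSTIC) | set(VR2_DIAGNOSTIC_5P) | set(VR2_DIAGNOSTIC_3P)
    first, last = aln.offset, aln.offset + aln.column_count - 1
    if all(first <= p <= last for p in diag_needed):
        for r in clone_aln.records:
            def at(pos: int) -> str:
                return r.seq[clone_aln.column_of_position(pos) - 1]

            vr1 = assign_compensatory_type(r.id, (at(103), at(159)), "VR1")
            vr2 = assign_compensatory_type(
                r.id,
                tuple(at(p) for p in VR2_DIAGNOSTIC_5P)
                + tuple(at(p) for p in VR2_DIAGNOSTIC_3P),
                "VR2",
            )
            comp[r.id] = {
                "VR1": vr1.type_label,
                "VR2": vr2.type_label,
                "intact_pairs": pairing_integrity(vr1) + pairing_integrity(vr2),
            }
    report["compensatory_types"] = comp

    # --- pairwise differences
    pw = stage("pairwise")(pairwise_differences, clone_aln)
    per_group_max = {}
    for g in groups:
        ids = [r.id for r in clone_aln.records if grouping[r.id] == g]
        if len(ids) >= 2:
            sub = pairwise_differences(clone_aln, ids)
            per_group_max[g] = {
                "max_substitutions": sub.max_substitutions,
                "max_pct_of_length": round(sub.max_pct_of_length, 1),
            }
    report["pairwise"] = {
        "identical_pairs": [list(p) for p in pw.identical_pairs],
        "max_substitutions": pw.max_substitutions,
        "per_group": per_group_max,
    }

    # --- distance tree with bootstrap
    if config.bootstrap_replicates:
        tree, ok = stage("tree")(
            bootstrap_support,
            clone_aln,
            config.distance_model,
            config.bootstrap_replicates,
            config.seed,
        )
        report["tree"] = {
            "model": config.distance_model,
            "newick": write_newick(tree),
            "bootstrap_replicates_used": ok,
        }

    # --- Phi recombination test
    if config.phi_permutations:
        phi = stage("phi")(
            phi_permutation_test,
            clone_aln,
            config.phi_window,
            config.phi_permutations,
            config.seed,
        )
        report["phi"] = {
            "statistic": phi.statistic,
            "w": phi.w,
            "n_informative": phi.n_informative,
            "n_permutations": phi.n_permutations,
            "p_value": phi.p_value,
        }
    return report


def fixture_report(
    seed: int = 1,
    bootstrap_replicates: int = 100,
    phi_permutations: int = 1000,
) -> dict:
    """Full pipeline run on the bundled study fixture."""
    aln = fx.reconstruct_alignment(include_consensus=True)
    config = RunConfig(
        alignment=aln,
        grouping=fx.GROUPS,
        consensus_ids=fx.CONSENSUS_IDS,
        pair_tables=tuple(fx.pair_tables()),
        vr_windows={"VR1": fx.VR1_WINDOW, "VR2": fx.VR2_WINDOW},
        bootstrap_replicates=bootstrap_replicates,
        phi_permutations=phi_permutations,
        seed=seed,
    )
    return run_all(config)


def write_report(report: dict, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return path
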