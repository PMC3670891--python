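"""End-to-end orchestration: simulate -> detect -> somatic -> stats.

Groups per-sample variant calls into tumor-replicate/normal triples by
the sample-id convention ``<case>-N`` / ``<case>-T1`` / ``<case>-T2``,
runs the verification logic, annotates somatic calls against their
amplicon (treated as a coding frame when its length allows), and writes
the cohort summary.  Also provides the truth-table comparison used to
benchmark the caller on synthetic cohorts.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .dipdetector import DetectorConfig, detect_reads
from .somatic_screen import GERMLINE, SOMATIC, annotate_variant, screen_case
from .synthetic_traces import SimulationConfig, SyntheticCohort, generate_cohort
from .trace_io import (
    MutationRecord,
    ReferenceSeq,
    SNPCatalog,
    TraceRead,
    write_mutation_table,
    write_variant_report,
)
from .variants import VariantCall

STATUS_COLUMNS = (
    "case_id",
    "sample_id",
    "reference",
    "position",
    "ref",
    "alt",
    "kind",
    "zygosity",
    "status",
)


def split_sample_id(sample_id: str) -> tuple[str, str]:
    """``C03-T1`` -> (``C03``, ``T1``); role must be N/T1/T2."""
    case, sep, role = sample_id.rpartition("-")
    if not sep or role not in ("N", "T1", "T2"):
        raise ValueError(f"sample id {sample_id!r} not of the form <case>-(N|T1|T2)")
    return case, role


def classify_cohort(
    calls: Sequence[VariantCall],
    catalog: SNPCatalog = SNPCatalog(),
    require_both_replicates: bool = True,
) -> pd.DataFrame:
    """Somatic/germline labels for every variant in a cohort's call set."""
    by_case: dict[str, dict[str, list[VariantCall]]] = defaultdict(
        lambda: {"N": [], "T1": [], "T2": []}
    )
    for call in calls:
        case, role = split_sample_id(call.sample_id)
        by_case[case][role].append(call)

    rows = []
    for case in sorted(by_case):
        groups = by_case[case]
        labelled = screen_case(
            groups["T1"],
            groups["T2"],
            groups["N"],
            catalog=catalog,
            case_id=case,
            require_both_replicates=require_both_replicates,
        )
        for call, status in labelled:
            rows.append(
                dict(
                    case_id=case,
                    sample_id=call.sample_id,
                    reference=call.reference,
                    position=call.position,
                    ref=call.ref,
                    alt=call.alt,
                    kind=call.kind,
                    zygosity=call.zygosity,
                    status=status,
                )
            )
    return pd.DataFrame(rows, columns=list(STATUS_COLUMNS))


def annotate_somatic(
    labelled: pd.DataFrame,
    references: Mapping[str, ReferenceSeq],
) -> list[MutationRecord]:
    """Annotate somatic calls whose amplicon can serve as a coding frame."""
    records: list[MutationRecord] = []
    for row in labelled[labelled.status == SOMATIC].itertuples():
        ref = references[row.reference]
        if len(ref.bases) % 3 != 0:
            continue
        cds = ReferenceSeq(name=ref.name, bases=ref.bases, role="CDS")
        call = VariantCall(
            sample_id=row.sample_id,
            reference=row.reference,
            position=int(row.position),
            ref=row.ref,
            alt=row.alt,
            zygosity=row.zygosity,
            kind=row.kind,
        )
        records.append(
            annotate_variant(call, cds, case_id=row.case_id, gene=row.reference)
        )
    return records


def evaluate_against_truth(labelled: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join predicted labels onto the planted truth table.

    Matching is on (case, amplicon, position, ref, alt); unrecovered
    variants get predicted = 'missed'.
    """
    pred = labelled.rename(columns={"reference": "amplicon", "status": "predicted"})[
        ["case_id", "amplicon", "position", "ref", "alt", "predicted"]
    ]
    merged = truth.merge(
        pred, on=["case_id", "amplicon", "position", "ref", "alt"], how="left"
    )
    merged["predicted"] = merged["predicted"].fillna("missed")
    return merged


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Full synthetic-cohort run; returns the paths of every artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim = SimulationConfig(
        **{
            **{
                f: getattr(config.simulation, f)
                for f in (
                    "peak_mean",
                    "allele_fraction",
                    "noise_sd",
                    "cross_talk",
                    "read_length",
                )
            },
            "seed": config.stage_seed("simulate"),
        }
    )
    cohort = generate_cohort(n_cases=config.n_cases, config=sim)
    cohort.write(outdir)

    refs = {r.name: r for r in cohort.references}
    calls = detect_reads(cohort.reads, refs, config.detector)
    calls_path = outdir / "calls.tsv"
    write_variant_report(calls, calls_path)

    labelled = classify_cohort(calls)
    status_path = outdir / "variant_status.tsv"
    labelled.to_csv(status_path, sep="\t", index=False)

    records = annotate_somatic(labelled, refs)
    mutations_path = outdir / "mutations.tsv"
    write_mutation_table(records, mutations_path)

    stats = summarize_cohort(labelled, n_cases=config.n_cases)
    stats_path = outdir / "stats.tsv"
    stats.to_csv(stats_path, sep="\t", index=False)

    comparison = evaluate_against_truth(labelled, cohort.truth)
    comparison_path = outdir / "truth_comparison.tsv"
    comparison.to_csv(comparison_path, sep="\t", index=False)

    return {
        "references": outdir / "references.fa",
        "traces": outdir / "traces.tsv",
        "truth": outdir / "truth.tsv",
        "calls": calls_path,
        "variant_status": status_path,
        "mutations": mutations_path,
        "stats": stats_path,
        "truth_comparison": comparison_path,
    }


def summarize_cohort(labelled: pd.DataFrame, n_cases: int) -> pd.DataFrame:
    """Per-amplicon somatic/germline case counts and fractions."""
    rows = []
    for (amplicon, status), group in sorted(
        labelled.groupby(["reference", "status"], sort=True)
    ):
        k = group["case_id"].nunique()
        rows.append(
            dict(
                amplicon=amplicon,
                status=status,
                cases=k,
                n=n_cases,
                fraction=round(k / n_cases, 4) if n_cases else 0.0,
            )
        )
    return pd.DataFrame(rows, columns=["amplicon", "status", "cases", "n", "fraction"])
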