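"""Reusable simulation studies backing validation of the pipeline.

These drive the synthetic-data generator through the production call paths
and measure recovery of the simulated truth.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .defs import load_definitions, packaged_amplicon_path
from .longread import run_longread_pipeline
from .sim import SimParams, default_barcodes, sim_long_reads, sim_population


def longread_recovery_study(
    n_replicates: int = 200,
    coverage: int = 50,
    sub_rate: float = 0.01,
    indel_rate: float = 0.005,
    seed: int = 0,
) -> Dict[str, float]:
    """Simulate one diploid sample per replicate, run the full long-read
    pipeline (demultiplex, length filter, align, diploid call) and score
    exact diplotype recovery."""
    from .io import read_fasta

    catalog, table = load_definitions()
    reference = read_fasta(packaged_amplicon_path())
    barcodes = default_barcodes(1, seed=7)
    pair_bc = barcodes["S000"]

    n_correct = 0
    n_called = 0
    for i in range(n_replicates):
        rep_seed = (seed + 9973 * (i + 1)) % (2**31)
        params = SimParams(
            n=1, coverage=coverage, sub_rate=sub_rate,
            indel_rate=indel_rate, seed=rep_seed,
        )
        pop = sim_population(params)
        truth = tuple(sorted((pop["allele1"][0], pop["allele2"][0])))
        reads, _ = sim_long_reads(
            truth, params, pair_bc, sample="S000",
            reference=reference, catalog=catalog, table=table,
        )
        calls, _, _ = run_longread_pipeline(
            reads, barcodes, reference, catalog, table
        )
        call = calls["S000"]
        if call.is_call:
            n_called += 1
            if tuple(sorted((call.allele1, call.allele2))) == truth:
                n_correct += 1
    return {
        "n_replicates": n_replicates,
        "n_called": n_called,
        "n_correct": n_correct,
        "recovery_fraction": n_correct / n_replicates,
    }


def loh_purity_boundary_study(
    threshold: float = 0.10,
    purities: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """Noise-free hemizygous-loss detection across tumor purities.

    Returns the empirical minimum detected purity, to compare with the
    closed-form boundary 2t/(0.5+t)."""
    from .loh import call_loh_baf
    from .sim import sim_baf_table

    catalog, table = load_definitions()
    if purities is None:
        purities = np.round(np.arange(0.02, 1.0001, 0.02), 4)
    detected = []
    for p in purities:
        params = SimParams(purity=float(p), baf_sd=0.0, aux_het_prob=1.0,
                           seed=1)
        baf = sim_baf_table(("*4", "*6A"), True, "*4", params, catalog, table)
        call = call_loh_baf(baf, threshold=threshold)
        detected.append(bool(call.loh))
    detected = np.asarray(detected)
    boundary = 2 * threshold / (0.5 + threshold)
    min_detected = float(purities[detected].min()) if detected.any() else 1.0
    consistent = all(
        d == (p >= boundary - 1e-9) for p, d in zip(purities, detected)
    )
    return {
        "threshold": threshold,
        "closed_form_boundary": boundary,
        "min_detected_purity": min_detected,
        "consistent_with_closed_form": consistent,
    }
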