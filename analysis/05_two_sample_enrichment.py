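"""Two-sample logo: global vs local enrichment and diagnostic positions.

Compares the 20 globally-acting to the 10 locally-acting simulated Lrp
orthologs per column and residue (Fisher's exact test, Bonferroni), writes
the full enrichment table, extracts the paper-style "X > Y" diagnostic
positions, and reports the test's empirical false-positive rate under a
shared-distribution null.
"""

import json
from pathlib import Path

from ortho_signature.seqio import read_fasta
from ortho_signature.synth import SimulationConfig
from ortho_signature.two_sample import (diagnostic_positions, null_calibration,
                                        two_sample_logo)

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    out = BASE / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    aln = read_fasta(BASE / "sim" / "family_alignment.fasta", gapped=True)
    truth = json.loads((BASE / "sim" / "family_truth.json").read_text())
    g = [i for i, o in truth["order_by_id"].items() if o in ("order1", "order2")]
    l = [i for i, r in truth["role_by_id"].items() if r == "local"]

    table = two_sample_logo(aln, g, l, alpha=0.05, correction="bonferroni",
                            group_A_label="global", group_B_label="local")
    table.to_frame().to_csv(out / "enrichment_table.tsv", sep="\t", index=False)
    diag = diagnostic_positions(table)
    (out / "diagnostic_positions.json").write_text(json.dumps(
        [{"position": p, "global": a, "local": b} for p, a, b in diag], indent=2))
    planted = {p[0] for p in SimulationConfig().planted_positions}
    hits = {p for p, _, _ in diag}
    notation = ", ".join(f"{a}{p} > {b}" for p, a, b in diag if p in planted)
    print(f"{table.n_tests} (position, residue) cells tested; "
          f"{len(table.significant_cells())} significant after Bonferroni")
    print(f"diagnostic positions: {len(diag)} total, "
          f"{len(hits & planted)}/8 planted recovered: {notation}")

    null = null_calibration(20, 10, 1000, seed=SEED)
    print(f"null calibration (20 vs 10, 1000 iid positions): per-cell "
          f"false-positive rate {null.cell_rate:.4f} at alpha=0.05 "
          f"(Fisher is conservative)")


if __name__ == "__main__":
    main()
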