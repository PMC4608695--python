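#!/usr/bin/env python
"""Rank the eight candidate reference genes with geNorm and NormFinder.

Reads the simulated panel from step 01 (generating it if absent),
converts candidate Cts to delta-Ct relative quantities (lowest-Ct sample
as calibrator), and reports: geNorm M values and stepwise ranking, the
pairwise-variation series V_{n/n+1} with the 0.15 cutoff, and NormFinder
stability values grouped by Zeitgeber time.  The expected outcome under
the generator's grading is Tubb2a/Rplp1 as the best pair — the combination
the downstream quantification normalizes against — and Gusb as the least
stable candidate.
"""

import argparse
import json
import subprocess
import sys
from pathlib import Path

import pandas as pd

from circaqpcr import data_model, quantify, refstab
from circaqpcr.synthetic import DEFAULT_REFERENCE_PANEL

ROOT = Path(__file__).resolve().parents[1]
CANDIDATES = [n for n, _, _ in DEFAULT_REFERENCE_PANEL]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    ct_csv = args.outdir / "sim_ct.csv"
    if not ct_csv.exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "01_simulate_panel.py"),
                        "--seed", str(args.seed), "--outdir", str(args.outdir)],
                       check=True)

    table = data_model.read_ct_table(ct_csv)
    agg, _ = data_model.aggregate_replicates(table)
    dq = quantify.delta_ct_quantities(agg[agg["gene"].isin(CANDIDATES)])

    gn = refstab.genorm(dq)
    nf = refstab.normfinder_stability(dq, groups=dq.meta["zt"])

    print("geNorm M values (lower = more stable):")
    for g, m in sorted(gn.m_values.items(), key=lambda kv: kv[1]):
        print(f"  {g:<8} {m:.3f}")
    print(f"geNorm ranking (best first): {gn.ranking}")
    print(f"geNorm best pair: {gn.best_pair}")
    print("pairwise variation V(n/n+1): "
          + ", ".join(f"V{n}/{n + 1}={v:.3f}" for n, v in gn.pairwise_variation))
    print(f"recommended number of reference genes "
          f"(cutoff {gn.cutoff}): {gn.recommended_count}")
    print("NormFinder stability (groups = ZT):")
    for g, s in sorted(nf.stability.items(), key=lambda kv: kv[1]):
        print(f"  {g:<8} {s:.3f}")
    print(f"NormFinder best gene: {nf.best_gene}; best pair: {nf.best_pair}")

    args.outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"gene": list(gn.m_values),
                  "genorm_m": list(gn.m_values.values()),
                  "normfinder_stability": [nf.stability[g]
                                           for g in gn.m_values]}) \
        .to_csv(args.outdir / "stability.tsv", sep="\t", index=False)
    (args.outdir / "stability.json").write_text(json.dumps({
        "genorm": {"m_values": gn.m_values, "ranking": gn.ranking,
                   "best_pair": list(gn.best_pair),
                   "pairwise_variation": gn.pairwise_variation,
                   "recommended_count": gn.recommended_count},
        "normfinder": {"stability": nf.stability, "best_gene": nf.best_gene,
                       "best_pair": list(nf.best_pair)},
    }, sort_keys=True, indent=1))
    print(f"wrote {args.outdir / 'stability.tsv'} and stability.json")


if __name__ == "__main__":
    main()
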