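"""Additive Bayesian network over variant, bilirubin, hypertension and
covariates.

Seven nodes (variant dosage, bilirubin, hypertension, sex, age, BMI, T2D)
are modeled with GLM node distributions; 200 hill-climbing searches from
random starts vote on directed edges, and the majority consensus keeps edges
present in at least half the locally optimal networks. The expected topology
is mediation: variant -> bilirubin -> hypertension with no direct
variant -> hypertension edge.
"""

import json
from pathlib import Path

from bilicausal import pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "run"

if __name__ == "__main__":
    pipeline.run_pipeline({"stages": ["simulate", "table1", "gwas", "abn"]},
                          out_dir=OUT)
    net = json.loads((OUT / "net.json").read_text())
    print("consensus edges (>=50% of searches):")
    for parent, child in net["consensus_edges"]:
        freq = net["edge_frequency"][f"{parent}->{child}"]
        print(f"  {parent} -> {child}   ({100 * freq:.0f}%)")
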