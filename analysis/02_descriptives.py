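"""Table-1 style descriptives of the simulated cohort, split by sex.

Continuous traits use Welch's t from group summaries; binary traits use
Pearson chi-square without continuity correction; the sex split itself uses
a goodness-of-fit test against a 50:50 split.
"""

from pathlib import Path

import pandas as pd

from bilicausal import pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "run"

if __name__ == "__main__":
    pipeline.run_pipeline({"stages": ["simulate", "table1"]}, out_dir=OUT)
    tbl = pd.read_csv(OUT / "table1.tsv", sep="\t")
    print(tbl.to_string(index=False))
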