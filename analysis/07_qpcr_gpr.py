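"""Score the miRNA qPCR panel with GPR, geNorm M and universal folds.

Censors Cp above the detection cutoff, ranks assay stability by geNorm
M, counts GPR hits per assay, and reports fold changes against the
universal normalizer; compares the planted fold change with the
recovered one.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS

from dparkit import io as dio
from dparkit import qpcr_gpr as qg


def main():
    data = RESULTS / "data"
    cp_table = qg.preprocess_cp(dio.read_cp_table(data / "qpcr_cp.csv"))
    truth = json.loads((data / "truth.json").read_text())["qpcr_fold"]

    m = qg.genorm_m_values(cp_table)
    scores = qg.gpr_scores(cp_table)
    folds = qg.fold_change_universal(cp_table)

    out = scores.join(m).join(folds)
    out.to_csv(RESULTS / "qpcr_gpr.tsv", sep="\t")
    print(out.round(3))
    changed = {a: f for a, f in truth.items() if f != 1.0}
    for assay, f in changed.items():
        print(f"{assay}: planted fold {f:.2f}, recovered {folds[assay]:.2f}, "
              f"GPR score {scores.loc[assay, 'score']:.2f}")


if __name__ == "__main__":
    main()
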