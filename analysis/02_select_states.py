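"""Choose the number of latent states.

Sweeps candidate state counts with the BIC-style penalised-likelihood
criterion (the free-energy surrogate) on the pooled, normalised time
series of a 16-subject subsample — enough pooled volumes for the
criterion to separate clearly while keeping the sweep quick.  The sweep
runs K = 3..8 here; the planted truth is K = 4 and the criterion should
land on it.

Requires analysis/01_simulate.py to have produced scratch/dataset.
"""

from pathlib import Path

import statedyn as sd
from statedyn import hmm

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "dataset"
RESULTS = ROOT / "results"
N_SUBSAMPLE = 16


def main() -> None:
    pairs = sd.read_dataset(DATA_DIR)
    series = [sd.normalize_timeseries(ts) for ts, _ in pairs[:N_SUBSAMPLE]]
    X, boundaries = sd.concatenate_subjects(series)
    print(f"pooled {len(series)} subjects -> {X.shape[0]} volumes, "
          f"{X.shape[1]} ROIs")

    report = hmm.select_k(
        X, boundaries, range(3, 9), seed=SEED, n_restarts=2, max_iter=60,
    )
    RESULTS.mkdir(exist_ok=True)
    report.table.to_csv(RESULTS / "model_selection.tsv", sep="\t",
                        index=False)
    print(report.table.to_string(index=False))
    print(f"selected K = {report.selected_K} "
          f"(criterion minimum; table -> results/model_selection.tsv)")


if __name__ == "__main__":
    main()
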