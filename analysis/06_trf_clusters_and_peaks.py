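"""Kernel-level group comparisons: spatiotemporal clusters and peaks.

Compares the fitted lexical-surprisal kernels between native and
second-language groups with a cluster-mass permutation test over
(source, lag), and extracts per-subject peaks of the spatially averaged
kernels for size/latency t-tests.
"""

from pathlib import Path

import h5py
import numpy as np

from speechtrf import io as stio
from speechtrf.stats import peak_analysis, trf_cluster_test

RESULTS = Path(__file__).resolve().parent.parent / "results"
PREDICTOR = 2  # lexical surprisal in the track order of step 01


def main() -> None:
    with h5py.File(RESULTS / "mtrfs.h5", "r") as f:
        kernels = f["kernels"][()]  # subject x predictor x source x lag
        lags_ms = f["lags_ms"][()]
        labels = [s.decode() for s in f["labels"][()]]
    ds = stio.load_group_dataset(RESULTS / "improvement_lexical_surprisal.h5")
    # native vs pooled second-language comparison
    l1l2 = ["L1" if l == "English" else "L2" for l in labels]
    trfs = kernels[:, PREDICTOR]  # subject x source x lag
    res = trf_cluster_test(trfs, l1l2, ds.space, lags_ms, n_perm=2000, seed=0)
    print(f"cluster-forming |t| > {res.t_critical:.2f}")
    if len(res.clusters):
        print(res.clusters.round(4).to_string(index=False))
        res.clusters.to_csv(RESULTS / "trf_clusters.tsv", sep="\t", index=False)
    else:
        print("no suprathreshold clusters")

    peaks = peak_analysis(trfs.mean(axis=1), lags_ms, l1l2)
    peaks.to_csv(RESULTS / "trf_peaks.tsv", sep="\t", index=False)
    print("\npeak comparison (spatially averaged kernels):")
    print(
        peaks.round(4).to_string(index=False)
        if len(peaks)
        else "no peaks above the prominence floor"
    )


if __name__ == "__main__":
    main()
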