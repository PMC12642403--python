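"""Fit cross-validated mTRFs for every subject and source.

Boosting with fourfold cross-validation and rotating validation segments;
per subject and source the model quality index q = 1 - l1(res)/l1(y) is
reported, and the averaged kernels are stored for the cluster/peak
analyses.
"""

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from speechtrf import io as stio
from speechtrf.basis import make_basis
from speechtrf.boosting import cross_validated_fit

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tracks = stio.load_tracks(RESULTS / "tracks.h5")
    with h5py.File(RESULTS / "responses.h5", "r") as f:
        responses = f["responses"][()]
        labels = [s.decode() for s in f["labels"][()]]
        fs = float(f.attrs["fs"])
    basis = make_basis(fs=fs)
    n_subj, _, n_src = responses.shape
    rows = []
    kernels = np.empty((n_subj, len(tracks), n_src, len(basis.lags)))
    for i in range(n_subj):
        res = cross_validated_fit(tracks, responses[i], 4, 0.005, basis)
        for s in range(n_src):
            kernels[i, :, s] = res.mtrf[s].kernels()
            rows.append(
                {"subject": i, "language": labels[i], "source": s,
                 "quality": res.quality[s]}
            )
        print(
            f"subject {i:2d} ({labels[i]:8s}): "
            f"q = {np.array2string(res.quality, precision=3)}"
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "fit_quality.tsv", sep="\t", index=False)
    with h5py.File(RESULTS / "mtrfs.h5", "w") as f:
        f.create_dataset("kernels", data=kernels)
        f.create_dataset("lags_ms", data=basis.lags_ms)
        f.create_dataset("labels", data=np.array(labels, dtype="S"))
        f["kernels"].attrs["axes"] = "subject x predictor x source x lag"
    print(
        f"mean quality index {table.quality.mean():.3f} "
        f"(range {table.quality.min():.3f}-{table.quality.max():.3f})"
    )


if __name__ == "__main__":
    main()
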