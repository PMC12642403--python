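"""Full-vs-reduced model comparison for the feature under investigation.

For every subject and source, the full predictor battery and a reduced
battery omitting lexical surprisal are fit with a shared partition; the
per-source difference in model quality index is that feature's
improvement map.  Maps are stored as a group dataset for the statistics
stage.
"""

from pathlib import Path

from speechtrf import io as stio
from speechtrf.pipeline import improvement_dataset
from speechtrf.simulate import simulate_group_study

import importlib.util as _ilu

_spec01 = _ilu.spec_from_file_location(
    "sim01", Path(__file__).resolve().parent / "01_simulate_study.py"
)
_sim01 = _ilu.module_from_spec(_spec01)
_spec01.loader.exec_module(_sim01)

RESULTS = Path(__file__).resolve().parent.parent / "results"
FEATURE = "lexical_surprisal"


def main() -> None:
    study = simulate_group_study(_sim01.SPEC)  # same spec/seed as step 01
    ds = improvement_dataset(study, FEATURE)
    stio.save_group_dataset(RESULTS / f"improvement_{FEATURE}.h5", ds)
    print(f"improvement maps for {FEATURE}: {ds.values.shape} (subject, source)")
    for g in dict.fromkeys(ds.labels):
        vals = ds.group(g)
        print(f"  {g:8s}: mean Delta q = {vals.mean():+.4f} (sd {vals.std():.4f})")
    print(f"-> {RESULTS / f'improvement_{FEATURE}.h5'}")


if __name__ == "__main__":
    main()
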