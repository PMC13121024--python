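#!/usr/bin/env python
"""Generate the synthetic multi-subject study used by the later stages.

Four conditions with graded arousal emulate an anaesthesia + thalamic-
stimulation experiment: the anaesthetic scales down inter-regional coupling
and raises common noise; stimulation partially restores coupling while the
drug remains present.  Writes the study (timeseries, connectome, truth map,
arousal scores, manifest) under results/study/.
"""

import argparse
from pathlib import Path

from phidyn.synthetic import DBS_CONDITIONS, save_study, synthetic_study

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "study")
    args = ap.parse_args()
    study = synthetic_study(n_subjects=15, n_regions=30,
                            condition_spec=DBS_CONDITIONS, seed=args.seed,
                            n_time=400)
    manifest = save_study(study, args.out)
    print(f"wrote study: {len(study.conditions)} conditions x "
          f"{study.n_subjects} subjects, {study.connectome.n} regions")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
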