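"""Generate the study design and example recordings.

Builds the full 25-subject design (10 insider-threat + 10 everyday-conflict
questions each, randomized order, empirical yes-rates) and writes it to
results/design.csv, then synthesizes one clean and one artifact-laden example
question recording for the downstream demonstration scripts.
"""

import argparse
from pathlib import Path

import eegintent as ei
from eegintent import io as eio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    design = ei.make_design(25, 10, 10, seed=args.seed)
    eio.save_design(design, args.out / "design.csv")
    df = design.to_frame()
    print(f"design: {len(df)} question trials over {df.subject.nunique()} subjects")
    print(f"  yes-rate insider : {(df[df.scenario_type=='insider'].answer=='yes').mean():.3f}")
    print(f"  yes-rate conflict: {(df[df.scenario_type=='conflict'].answer=='yes').mean():.3f}")
    print(f"  excluded (no response): {(~df.responded).sum()}")

    # one subject's first question, clean and with artifacts, 10 s for speed
    effects = ei.EffectSpec(intent_effect=0.5, scenario_effect=0.5)
    sub_design = ei.ExperimentDesign(design.subject_trials("S01")[:1])
    rec_dir = args.out / "example_recordings"
    for with_artifacts, tag in ((False, "clean"), (True, "raw")):
        rec = next(ei.synthesize_experiment(sub_design, effects, args.seed,
                                            duration=10.0,
                                            with_artifacts=with_artifacts))
        rec.subject = f"S01{tag}"
        path = eio.save_recording(rec, rec_dir)
        print(f"wrote {path} ({rec.signal.shape[0]} channels x {rec.n_samples} samples)")


if __name__ == "__main__":
    main()
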