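"""Export the 24-rhythm stimulus set and verify its structure.

Writes results/stimuli/stimulus_table.csv and prints the per-condition and
per-set counts plus the unit-sum check for the integer-ratio rhythms.
Pass --wav to also render the long (18-s) stimuli as 16-bit PCM WAV files.
"""

import argparse
import math
from pathlib import Path

from beattag import rhythms as R


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/stimuli"))
    ap.add_argument("--wav", action="store_true")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = R.builtin_rhythm_table()
    R.write_stimulus_table(table, args.out / "stimulus_table.csv")

    print(f"{len(table)} unique rhythms")
    for cond in R.CONDITIONS:
        n = sum(r.condition == cond for r in table)
        print(f"  {cond:>6}: {n} rhythms")
    for set_id in (1, 2, 3, 4):
        members = [r for r in table if set_id in r.set_ids]
        per = {c: sum(r.condition == c for r in members) for c in R.CONDITIONS}
        print(f"  set {set_id}: {len(members)} rhythms ({per})")
    ok = all(
        math.isclose(r.total_units, 12.0)
        for r in table if r.condition in ("strong", "weak")
    )
    print(f"all strong/weak rhythms sum to 12 units (3000 ms): {ok}")

    if args.wav:
        for k, spec in enumerate(table):
            R.write_wav(R.make_long(spec), args.out / f"{spec.condition}_{k:02d}.wav")
        print(f"wrote {len(table)} WAV files to {args.out}")


if __name__ == "__main__":
    main()
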