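#!/usr/bin/env python
"""Generate the synthetic panel set used by the downstream analyses.

Emulates the structure of the study material: a 551-year master
(1100-1650 CE), a 210-ring board ending 1606 at the heartwood/sapwood
border ("GNM") and a 231-ring board with 8 sapwood rings ending 1614
("RM") cut from one tree, plus a 99-ring heartwood board ending 1601
("MH") from a second tree.  Writes Tucson RWL files and the construction
truth to results/synthetic/.
"""

import argparse
import json
from pathlib import Path

from dendrodate import generate_boards, generate_master, study_scenario, write_series

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20)
    args = parser.parse_args()

    out = ROOT / "results" / "synthetic"
    out.mkdir(parents=True, exist_ok=True)

    scenario = study_scenario(seed=args.seed)
    master = generate_master(scenario)
    boards, truth = generate_boards(scenario)

    write_series([master], out / "master.rwl")
    for board in boards:
        write_series([board], out / f"{board.series_id}.rwl")
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    print(f"master: {master.first_ring_year}-{master.last_ring_year} "
          f"({master.n} years)")
    for board in boards:
        print(f"{board.series_id}: {board.n} rings, "
              f"{board.first_ring_year}-{board.last_ring_year}, "
              f"{board.n_sapwood} sapwood"
              + (" (ends at hw/sw border)" if board.hw_sw_border_is_last_ring else ""))
    print(f"wrote RWL files and truth.json to {out}")


if __name__ == "__main__":
    main()
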