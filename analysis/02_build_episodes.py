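#!/usr/bin/env python
"""Chain the injury records into censored return-to-play episodes.

Each injury opens an episode at its RTP date; the episode ends with the next
non-contact injury in the same season (observed event) or is censored at the
next contact injury or the season's last match. Prints the accounting that a
register study reports: observed vs censored, censor reasons, and the
severity-by-position cross-tab of observed events.
"""

import logging
from pathlib import Path

from rtphazard import (
    build_episodes,
    default_calendar,
    episode_summary,
    read_records_csv,
    write_episodes_csv,
)

OUT = Path("results")


def main() -> None:
    logging.basicConfig(level=logging.ERROR)
    records = read_records_csv(OUT / "cohort.csv")
    episodes = build_episodes(records, default_calendar())
    write_episodes_csv(episodes, OUT / "episodes.csv")

    s = episode_summary(episodes)
    print(f"{s['n_episodes']} episodes: {s['n_observed']} observed events, "
          f"{s['n_censored']} censored")
    for reason, n in s["censor_reasons"].items():
        print(f"  censored at {reason}: {n} ({100 * n / s['n_episodes']:.1f}%)")
    print("observed-event severity shares:",
          {k: round(v, 3) for k, v in s["observed_severity_shares"].items()})
    print(f"wrote {OUT / 'episodes.csv'}")


if __name__ == "__main__":
    main()
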