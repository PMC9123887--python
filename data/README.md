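# Drop-in study data

The reproduction checks in `tests/test_acceptance.py` compare against the
original field study's published per-hour detection dataset, which is not
redistributed with this package.  To run them, place two CSV files here:

## `study_dp10m_hourly.csv`

One row per monitored hour:

| column          | type                | meaning                                   |
|-----------------|---------------------|-------------------------------------------|
| `hour_start`    | ISO-8601 datetime   | top of the monitored hour (local time)    |
| `deployment_id` | token               | deployment the hour belongs to            |
| `dp10m`         | integer 0–6         | detection-positive 10-min intervals       |
| `effort_min`    | integer 1–60        | recorded minutes in the hour              |
| `moon`          | float in [0,1)      | optional; moon-cycle fraction of the hour |

## `study_clusters.csv`

Published deployment→environmental-cluster memberships:

| column          | type  | meaning                                      |
|-----------------|-------|-----------------------------------------------|
| `deployment_id` | token | must match the hourly table                   |
| `cluster`       | token | one of `May-Jul`, `Aug-Oct`, `Oct-Mar`        |

Without these files the four study-reproduction tests fail with a message
pointing here; every other test runs on synthetic data generated at test
time.
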