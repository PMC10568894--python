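"""Shared fixtures: a hand-countable 12-row registry extract.

The toy extract is designed so every cohort rule is exercised and every
expected number can be tallied by hand:

population (8 patients, 5 female):
  p1 female 1990 | p2 male 1985 | p3 female 2000 (17 in 2017, 19 in 2019)
  p4 female 1960 | p5 male 1953 (64 in 2017, 66 in 2019) | p6 female 1975
  p7 male 1995   | p8 female 1980

consultations (12 rows):
   1 p1 2019-03-04 P74;P03  -> pandemic member; analysed (P74, 2019-W10)
   2 p1 2019-03-05 P74      -> analysed (same ISO week -> W10 count 2)
   3 p2 2019-06-10 P03      -> membership via symptom code only; row dropped
   4 p2 2020-04-01 P76      -> analysed (2020-W14)
   5 p3 2019-07-15 P76      -> member aged 19; analysed (2019-W29)
   6 p4 2018-05-02 P79      -> no 2019 row: p4 not a pandemic member
   7 p4 2020-02-10 P82      -> non-member row, dropped
   8 p5 2019-09-09 P74      -> p5 aged 66 at inclusion: excluded, dropped
   9 p6 2019-11-11 P01      -> member via symptom code; nothing analysed
  10 p7 2019-12-02 P86;P74  -> member; counts in both P86 and P74 (2019-W49)
  11 p7 2021-01-20 P86      -> analysed (2021-W03)
  12 p8 2017-01-16 P76      -> pre-pandemic member only

Pandemic cohort: {p1, p2, p3, p6, p7} (5 members); retained pandemic
consultations: rows 1, 2, 4, 5, 10, 11 (6 rows over 4 distinct patients,
50% women).  Pre-pandemic cohort: {p8}, 1 retained row.
"""

import pytest

from mhconsult import PANDEMIC_SPEC, PRE_PANDEMIC_SPEC, build_dataset
from mhconsult.registry_io import read_consultations_frame, read_population_frame

POPULATION_CSV = """\
patient_id,gender,birth_year
p1,female,1990
p2,male,1985
p3,female,2000
p4,female,1960
p5,male,1953
p6,female,1975
p7,male,1995
p8,female,1980
"""

CONSULTATIONS_CSV = """\
patient_id,date,diagnosis_codes,contact_type
p1,2019-03-04,P74;P03,gp_day
p1,2019-03-05,P74,gp_e_day
p2,2019-06-10,P03,gp_day
p2,2020-04-01,P76,gp_day
p3,2019-07-15,P76,ooh_day
p4,2018-05-02,P79,gp_day
p4,2020-02-10,P82,gp_evening
p5,2019-09-09,P74,gp_day
p6,2019-11-11,P01,ooh_e_evening
p7,2019-12-02,P86;P74,gp_day
p7,2021-01-20,P86,gp_e_day
p8,2017-01-16,P76,gp_day
"""

PANDEMIC_COHORT = {"p1", "p2", "p3", "p6", "p7"}


@pytest.fixture
def toy_paths(tmp_path):
    cons = tmp_path / "consultations.csv"
    pop = tmp_path / "population.csv"
    cons.write_text(CONSULTATIONS_CSV)
    pop.write_text(POPULATION_CSV)
    return cons, pop


@pytest.fixture
def toy_frames(toy_paths):
    cons, pop = toy_paths
    return read_consultations_frame(cons), read_population_frame(pop)


@pytest.fixture
def pandemic_dataset(toy_frames):
    cons, pop = toy_frames
    return build_dataset(cons, pop, PANDEMIC_SPEC, "pandemic")


@pytest.fixture
def prepandemic_dataset(toy_frames):
    cons, pop = toy_frames
    return build_dataset(cons, pop, PRE_PANDEMIC_SPEC, "pre_pandemic")
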