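"""Column names and variable sets shared across the pipeline.

The tidy CSV dialect is the package's canonical on-disk exchange format: one
food-item row per line for recall data, one row per participant for the
participant table. NHANES SAS-transport files are translated into the same
in-memory frames by :mod:`recallvar.ingest`.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# tidy_csv food-item table (one row per food consumed)
# ---------------------------------------------------------------------------
PID = "participant_id"
DAY = "day"
TIME = "event_time_hours"
FOOD_CODE = "food_code"
GRAMS = "grams"
KCAL = "kcal"
CARB = "carb_g"
PROTEIN = "protein_g"
FAT = "fat_g"
FIBRE = "fibre_g"

ITEM_COLUMNS = [PID, DAY, TIME, FOOD_CODE, GRAMS, KCAL, CARB, PROTEIN, FAT, FIBRE]
MACRO_COLUMNS = [CARB, PROTEIN, FAT, FIBRE]

# ---------------------------------------------------------------------------
# tidy_csv participant table (one row per participant)
# ---------------------------------------------------------------------------
GENDER = "gender"
AGE = "age_years"
INCOME = "income_pir"
EDUCATION = "education"
ETHNICITY = "ethnicity"
CHILDREN = "children_in_household"
FI_SCORE = "fi_score"
FI_BINARY = "fi_binary"
FI_FOURLEVEL = "fi_fourlevel"
BMI = "bmi"
WEIGHT = "survey_weight"
N_RECALL_DAYS = "n_recall_days"

PARTICIPANT_COLUMNS = [
    PID, GENDER, AGE, INCOME, EDUCATION, ETHNICITY, CHILDREN,
    FI_SCORE, BMI, WEIGHT,
]

FI_ITEM_PREFIX = "fi_item_"  # fi_item_1 .. fi_item_10 (alternative to fi_score)

SECURE = "secure"
INSECURE = "insecure"

#: default sociodemographic adjustment set used throughout
COVARIATES = [AGE, INCOME, EDUCATION, ETHNICITY, CHILDREN]
#: covariates entered as unordered categorical factors
CATEGORICAL_COVARIATES = [EDUCATION, ETHNICITY]

# ---------------------------------------------------------------------------
# derived per-participant feature names (the 16 consumption-pattern variables)
# ---------------------------------------------------------------------------
ENERGY = "energy_kcal"
REL_CARB = "relative_carbohydrate_g"
REL_PROTEIN = "relative_protein_g"
REL_FAT = "relative_fat_g"
REL_FIBRE = "relative_fibre_g"

FIRST_CE = "first_ce_time_h"
N_CES = "n_ces"
MEAN_FOODS_PER_CE = "mean_foods_per_ce"
SD_FOODS_PER_CE = "sd_foods_per_ce"
SD_TIME_GAP = "sd_time_gap_min"
SD_ENERGY_PER_CE = "sd_energy_per_ce_kcal"
MEAN_TIME_GAP = "mean_time_gap_min"  # fully determined by FIRST_CE and N_CES; kept
                                     # for the interday difference, not as an outcome

IDD_ENERGY = "idd_energy_kcal"
IDD_FIRST_CE = "idd_first_ce_h"
IDD_N_FOODS = "idd_n_foods"
IDD_N_CES = "idd_n_ces"
IDD_MEAN_GAP = "idd_mean_gap_min"

#: raw day-averaged intake used for residualisation (not outcomes themselves)
TOTAL_GRAMS = "total_grams"
N_FOODS_DAY = "n_foods_day"
CARB_G = "carbohydrate_g"
PROTEIN_G = "protein_total_g"
FAT_G = "fat_total_g"
FIBRE_G = "fibre_total_g"

AMOUNT_VARS = [ENERGY, REL_CARB, REL_PROTEIN, REL_FAT, REL_FIBRE]
INTRADAY_VARS = [FIRST_CE, N_CES, MEAN_FOODS_PER_CE, SD_FOODS_PER_CE,
                 SD_TIME_GAP, SD_ENERGY_PER_CE]
INTERDAY_VARS = [IDD_ENERGY, IDD_FIRST_CE, IDD_N_FOODS, IDD_N_CES, IDD_MEAN_GAP]

ALL_FEATURES = AMOUNT_VARS + INTRADAY_VARS + INTERDAY_VARS

OUTCOME_SETS = {
    "amounts": AMOUNT_VARS,
    "intraday": INTRADAY_VARS,
    "interday": INTERDAY_VARS,
}

RELATIVE_OF = {REL_CARB: CARB_G, REL_PROTEIN: PROTEIN_G,
               REL_FAT: FAT_G, REL_FIBRE: FIBRE_G}
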