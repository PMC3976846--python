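{
 "_note": "Study grouping of 147 clinical symptoms into 27 syndrome groups. Group names, sizes and exclusivity flags follow the published HCC study configuration; member symptom names are documented only for 'Lip color', 'Emotion', 'Cardiothoracic condition' and 'Diet' - the remaining member names are synthetic placeholders (abbrev_i).",
 "groups": [
  {
   "group_name": "Lip color",
   "abbreviation": "LC",
   "members": [
    "lip_color_is_pale",
    "lip_color_is_red",
    "lip_color_is_pink",
    "lip_color_is_dark_purple"
   ],
   "exclusive": true
  },
  {
   "group_name": "Tongue color",
   "abbreviation": "Tc",
   "members": [
    "Tc_1",
    "Tc_2",
    "Tc_3",
    "Tc_4"
   ],
   "exclusive": true
  },
  {
   "group_name": "Appearance of tongue-1",
   "abbreviation": "At1",
   "members": [
    "At1_1",
    "At1_2",
    "At1_3"
   ],
   "exclusive": false
  },
  {
   "group_name": "Appearance of tongue-2",
   "abbreviation": "At2",
   "members": [
    "At2_1",
    "At2_2",
    "At2_3",
    "At2_4",
    "At2_5"
   ],
   "exclusive": false
  },
  {
   "group_name": "Coated tongue color",
   "abbreviation": "Ctc",
   "members": [
    "Ctc_1",
    "Ctc_2",
    "Ctc_3"
   ],
   "exclusive": true
  },
  {
   "group_name": "Texture of coated tongue",
   "abbreviation": "Tct",
   "members": [
    "Tct_1",
    "Tct_2",
    "Tct_3",
    "Tct_4",
    "Tct_5",
    "Tct_6",
    "Tct_7"
   ],
   "exclusive": false
  },
  {
   "group_name": "Position of coated tongue",
   "abbreviation": "Pct",
   "members": [
    "Pct_1",
    "Pct_2",
    "Pct_3",
    "Pct_4",
    "Pct_5"
   ],
   "exclusive": false
  },
  {
   "group_name": "The color of complexion",
   "abbreviation": "Coc",
   "members": [
    "Coc_1",
    "Coc_2",
    "Coc_3",
    "Coc_4",
    "Coc_5",
    "Coc_6",
    "Coc_7",
    "Coc_8"
   ],
   "exclusive": false
  },
  {
   "group_name": "Whole body condition",
   "abbreviation": "Wbc",
   "members": [
    "Wbc_1",
    "Wbc_2",
    "Wbc_3",
    "Wbc_4",
    "Wbc_5",
    "Wbc_6",
    "Wbc_7",
    "Wbc_8"
   ],
   "exclusive": false
  },
  {
   "group_name": "Odor",
   "abbreviation": "Od",
   "members": [
    "Od_1"
   ],
   "exclusive": false
  },
  {
   "group_name": "Chilly",
   "abbreviation": "Ch",
   "members": [
    "Ch_1"
   ],
   "exclusive": false
  },
  {
   "group_name": "Hectic fever",
   "abbreviation": "Hf",
   "members": [
    "Hf_1"
   ],
   "exclusive": false
  },
  {
   "group_name": "Fever",
   "abbreviation": "Fe",
   "members": [
    "Fe_1"
   ],
   "exclusive": false
  },
  {
   "group_name": "Sweating",
   "abbreviation": "St",
   "members": [
    "St_1",
    "St_2"
   ],
   "exclusive": false
  },
  {
   "group_name": "Facial features",
   "abbreviation": "Ff",
   "members": [
    "Ff_1",
    "Ff_2",
    "Ff_3",
    "Ff_4",
    "Ff_5",
    "Ff_6",
    "Ff_7",
    "Ff_8",
    "Ff_9",
    "Ff_10",
    "Ff_11",
    "Ff_12",
    "Ff_13"
   ],
   "exclusive": false
  },
  {
   "group_name": "Cardiothoracic condition",
   "abbreviation": "Ca",
   "members": [
    "tightness_in_the_chest",
    "shortness_of_breath",
    "palpitations",
    "pain_in_the_chest"
   ],
   "exclusive": false
  },
  {
   "group_name": "Sternocostal and abdominal pain",
   "abbreviation": "Sap",
   "members": [
    "Sap_1",
    "Sap_2",
    "Sap_3",
    "Sap_4",
    "Sap_5",
    "Sap_6",
    "Sap_7",
    "Sap_8",
    "Sap_9",
    "Sap_10",
    "Sap_11",
    "Sap_12",
    "Sap_13",
    "Sap_14",
    "Sap_15",
    "Sap_16"
   ],
   "exclusive": false
  },
  {
   "group_name": "Diet",
   "abbreviation": "Diet",
   "members": [
    "anorexia",
    "tired_of_greasy",
    "nausea",
    "hiccups",
    "acid_reflux",
    "water_reflux",
    "gastric_discomfort"
   ],
   "exclusive": false
  },
  {
   "group_name": "Defecate and urine",
   "abbreviation": "Du",
   "members": [
    "Du_1",
    "Du_2",
    "Du_3",
    "Du_4",
    "Du_5",
    "Du_6",
    "Du_7",
    "Du_8",
    "Du_9",
    "Du_10"
   ],
   "exclusive": false
  },
  {
   "group_name": "Sleep",
   "abbreviation": "Slp",
   "members": [
    "Slp_1",
    "Slp_2"
   ],
   "exclusive": false
  },
  {
   "group_name": "Emotion",
   "abbreviation": "NEs",
   "members": [
    "irritability",
    "depression",
    "sigh"
   ],
   "exclusive": false
  },
  {
   "group_name": "Skin of the limbs",
   "abbreviation": "Sl",
   "members": [
    "Sl_1",
    "Sl_2",
    "Sl_3",
    "Sl_4",
    "Sl_5",
    "Sl_6",
    "Sl_7",
    "Sl_8",
    "Sl_9",
    "Sl_10"
   ],
   "exclusive": false
  },
  {
   "group_name": "Bump in ribs",
   "abbreviation": "Bir",
   "members": [
    "Bir_1"
   ],
   "exclusive": false
  },
  {
   "group_name": "Ascites",
   "abbreviation": "Ass",
   "members": [
    "Ass_1"
   ],
   "exclusive": false
  },
  {
   "group_name": "Pleural effusion",
   "abbreviation": "Pe",
   "members": [
    "Pe_1"
   ],
   "exclusive": false
  },
  {
   "group_name": "Pulse condition in left",
   "abbreviation": "Pcle",
   "members": [
    "Pcle_1",
    "Pcle_2",
    "Pcle_3",
    "Pcle_4",
    "Pcle_5",
    "Pcle_6",
    "Pcle_7",
    "Pcle_8",
    "Pcle_9",
    "Pcle_10",
    "Pcle_11",
    "Pcle_12",
    "Pcle_13"
   ],
   "exclusive": false
  },
  {
   "group_name": "Pulse condition in right",
   "abbreviation": "Pcrt",
   "members": [
    "Pcrt_1",
    "Pcrt_2",
    "Pcrt_3",
    "Pcrt_4",
    "Pcrt_5",
    "Pcrt_6",
    "Pcrt_7",
    "Pcrt_8",
    "Pcrt_9",
    "Pcrt_10",
    "Pcrt_11",
    "Pcrt_12",
    "Pcrt_13"
   ],
   "exclusive": false
  }
 ]
}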