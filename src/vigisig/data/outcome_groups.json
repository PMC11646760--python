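{
  "_comment": "Mock outcome-group dictionary. Group structure follows the published 21 cardiovascular adverse-event groups; the term lists are synthetic lowercase stand-ins for the licensed MedDRA 25.1 queries named in each group's source label and are NOT the licensed terminology. The first term of each group is unique to that group (the simulator uses it as the group's primary coded term).",
  "groups": {
    "Hypertension": {
      "source": "Hypertension (SMQ narrow 25.1)",
      "terms": ["hypertension", "blood pressure increased", "hypertensive crisis", "hypertensive emergency"]
    },
    "Arterial embolism and thrombosis": {
      "source": "Embolic and thrombotic events, arterial (SMQ narrow 25.1)",
      "terms": ["arterial thrombosis", "arterial embolism", "peripheral artery thrombosis", "carotid artery occlusion"]
    },
    "Myocardial infarction": {
      "source": "Myocardial infarction (SMQ narrow 25.1)",
      "terms": ["myocardial infarction", "acute myocardial infarction", "acute coronary syndrome", "coronary artery occlusion"]
    },
    "Central nervous system ischemia": {
      "source": "Ischemic central nervous system vascular conditions (SMQ narrow 25.1)",
      "terms": ["cerebral ischaemia", "ischaemic stroke", "cerebral infarction", "transient ischaemic attack"]
    },
    "Bradyarrhythmias": {
      "source": "Bradyarrhythmia terms, nonspecific (SMQ narrow 25.1); Conduction defects (SMQ narrow 25.1); Disorders of sinus node function (SMQ narrow 25.1)",
      "terms": ["bradycardia", "sinus bradycardia", "atrioventricular block", "sinus node dysfunction"]
    },
    "Endocardial disorders": {
      "source": "Endocardial disorders (HLGT 25.1)",
      "terms": ["endocarditis non-infective", "mitral valve incompetence", "aortic valve incompetence", "endocardial fibrosis"]
    },
    "Supraventricular tachyarrhythmias": {
      "source": "Supraventricular tachyarrhythmias (SMQ narrow 25.1)",
      "terms": ["atrial fibrillation", "atrial flutter", "supraventricular tachycardia", "sinus tachycardia"]
    },
    "Ventricular tachyarrhythmias": {
      "source": "Ventricular tachyarrhythmias (SMQ narrow 25.1)",
      "terms": ["ventricular tachycardia", "ventricular fibrillation", "torsade de pointes", "ventricular arrhythmia"]
    },
    "Cardiomyopathy": {
      "source": "Cardiomyopathy (SMQ narrow 25.1)",
      "terms": ["cardiomyopathy", "dilated cardiomyopathy", "ejection fraction decreased", "ventricular dysfunction"]
    },
    "Respiratory failure": {
      "source": "Respiratory failure (SMQ narrow 25.1)",
      "terms": ["respiratory failure", "acute respiratory failure", "respiratory arrest", "hypoxia"]
    },
    "Heart failure": {
      "source": "Cardiac failure (SMQ narrow 25.1)",
      "terms": ["cardiac failure", "cardiac failure congestive", "cardiac failure acute", "pulmonary oedema"]
    },
    "Shock": {
      "source": "Shock-associated circulatory or cardiac conditions (excl torsade de pointes) (SMQ narrow 25.1)",
      "terms": ["shock", "cardiogenic shock", "circulatory collapse", "distributive shock"]
    },
    "Myocarditis": {
      "source": "Non-infectious myocarditis (HLT 25.1)",
      "terms": ["myocarditis", "autoimmune myocarditis", "eosinophilic myocarditis", "giant cell myocarditis"]
    },
    "Pericarditis": {
      "source": "Non-infectious pericarditis (HLT 25.1) and pericardial disorders NEC (HLT 25.1)",
      "terms": ["pericarditis", "pericardial effusion", "cardiac tamponade", "pericardial haemorrhage"]
    },
    "Venous embolism and thrombosis": {
      "source": "Embolic and thrombotic events, venous (SMQ narrow 25.1)",
      "terms": ["deep vein thrombosis", "pulmonary embolism", "venous thrombosis", "thrombophlebitis"]
    },
    "Hemorrhage (clinical events)": {
      "source": "Hemorrhage terms (excl laboratory terms) (SMQ narrow 25.1)",
      "terms": ["haemorrhage", "gastrointestinal haemorrhage", "epistaxis", "haematuria", "haemorrhage intracranial"]
    },
    "Bleeding-related laboratory abnormalities": {
      "source": "Hemorrhage laboratory terms (SMQ narrow 25.1)",
      "terms": ["haemoglobin decreased", "platelet count decreased", "international normalised ratio increased", "haematocrit decreased"]
    },
    "Cerebral hemorrhage": {
      "source": "Hemorrhagic central nervous system vascular conditions (SMQ narrow 25.1)",
      "terms": ["cerebral haemorrhage", "haemorrhage intracranial", "haemorrhagic stroke", "subarachnoid haemorrhage"]
    },
    "Pulmonary hypertension": {
      "source": "Pulmonary hypertension (SMQ narrow 25.1)",
      "terms": ["pulmonary hypertension", "pulmonary arterial hypertension", "right ventricular failure"]
    },
    "Vasculitis": {
      "source": "Vasculitis (SMQ narrow 25.1)",
      "terms": ["vasculitis", "cutaneous vasculitis", "hypersensitivity vasculitis", "aortitis"]
    },
    "Temporal arteritis/Polymyalgia rheumatica": {
      "source": "Polymyalgia rheumatica (PT 25.1) and Giant cell arteritis (PT 25.1)",
      "terms": ["polymyalgia rheumatica", "giant cell arteritis"]
    }
  }
}
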