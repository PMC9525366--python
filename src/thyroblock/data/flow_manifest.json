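{
  "comment": "Maps published flow row labels to compartment-pair identifiers. wc_gated flows are the saturable carrier routes into a thyroid gland that are shut by the Wolff-Chaikoff block. 'Blood to thyroid iodide' also appears in the constant first-order table with its linear-regime rate constant; it is the same carrier-mediated flow, so the loader keeps only the Michaelis-Menten version (duplicate_of_carrier).",
  "flows": {
    "Blood to thyroid iodide": {"source": "blood", "target": "thyroid_iodide", "law": "michaelis_menten", "wc_gated": true, "gland": "maternal"},
    "Blood to thyroid organic iodine": {"source": "blood", "target": "thyroid_organic", "law": "michaelis_menten", "wc_gated": true, "gland": "maternal"},
    "Blood to salivary gland": {"source": "blood", "target": "salivary_glands", "law": "michaelis_menten", "wc_gated": false},
    "Blood to gastric secretory cells": {"source": "blood", "target": "gastric_secretory", "law": "michaelis_menten", "wc_gated": false},
    "Blood to placenta iodide": {"source": "blood", "target": "uteroplacental_iodide", "law": "michaelis_menten", "wc_gated": false},
    "Fetal iodide to fetal thyroid": {"source": "fetal_iodide", "target": "fetal_thyroid", "law": "michaelis_menten", "wc_gated": true, "gland": "fetal"},
    "Blood to kidneys": {"source": "blood", "target": "kidneys", "law": "first_order"},
    "Blood to amniotic fluid iodide": {"source": "blood", "target": "amniotic_iodide", "law": "first_order"},
    "Organic iodine in other to iodide in other": {"source": "organic_other", "target": "iodide_other", "law": "first_order"},
    "Organic iodine in other to upper large intestine": {"source": "organic_other", "target": "upper_large_intestine", "law": "first_order"},
    "Organic iodine in other to uteroplacental unit organic iodine": {"source": "organic_other", "target": "uteroplacental_organic", "law": "first_order"},
    "Organic iodine in other to amniotic fluid organic iodine": {"source": "organic_other", "target": "amniotic_organic", "law": "first_order"},
    "Uteroplacental unit iodide to blood": {"source": "uteroplacental_iodide", "target": "blood", "law": "first_order"},
    "Uteroplacental unit iodide to fetal iodide": {"source": "uteroplacental_iodide", "target": "fetal_iodide", "law": "first_order"},
    "Uteroplacental unit organic iodine to organic iodine in other": {"source": "uteroplacental_organic", "target": "organic_other", "law": "first_order"},
    "Fetal iodide to uteroplacental unit iodide": {"source": "fetal_iodide", "target": "uteroplacental_iodide", "law": "first_order"},
    "Thyroid organic iodine to organic iodine in other": {"source": "thyroid_organic", "target": "organic_other", "law": "first_order"},
    "Amniotic fluid iodide to blood": {"source": "amniotic_iodide", "target": "blood", "law": "first_order"},
    "Amniotic fluid iodide to fetal iodide": {"source": "amniotic_iodide", "target": "fetal_iodide", "law": "first_order"},
    "Amniotic fluid organic iodine to organic iodine in other": {"source": "amniotic_organic", "target": "organic_other", "law": "first_order"},
    "Amniotic fluid organic iodine to fetal iodide": {"source": "amniotic_organic", "target": "fetal_iodide", "law": "first_order"},
    "Stomach to blood": {"source": "stomach", "target": "blood", "law": "first_order"},
    "Stomach to small intestine": {"source": "stomach", "target": "small_intestine", "law": "first_order"},
    "Small intestine to blood": {"source": "small_intestine", "target": "blood", "law": "first_order"},
    "Small intestine to upper large intestine": {"source": "small_intestine", "target": "upper_large_intestine", "law": "first_order"},
    "Blood to iodide in other": {"source": "blood", "target": "iodide_other", "law": "first_order"},
    "Blood to ovaries": {"source": "blood", "target": "ovaries", "law": "first_order"},
    "Iodide in other to blood": {"source": "iodide_other", "target": "blood", "law": "first_order"},
    "Thyroid iodide to blood": {"source": "thyroid_iodide", "target": "blood", "law": "first_order"},
    "Ovaries to blood": {"source": "ovaries", "target": "blood", "law": "first_order"},
    "Salivary glands to stomach": {"source": "salivary_glands", "target": "stomach", "law": "first_order"},
    "Gastric secretory cells to stomach": {"source": "gastric_secretory", "target": "stomach", "law": "first_order"},
    "Kidneys to urinary bladder": {"source": "kidneys", "target": "urinary_bladder", "law": "first_order"},
    "Fetal thyroid to fetal organic iodine": {"source": "fetal_thyroid", "target": "fetal_organic", "law": "first_order"},
    "Fetal organic iodine to fetal iodide": {"source": "fetal_organic", "target": "fetal_iodide", "law": "first_order"},
    "Upper large intestine to lower large intestine": {"source": "upper_large_intestine", "target": "lower_large_intestine", "law": "first_order"},
    "Lower large intestine to feces": {"source": "lower_large_intestine", "target": "feces", "law": "first_order"},
    "Urinary bladder to urine": {"source": "urinary_bladder", "target": "urine", "law": "first_order"}
  },
  "duplicate_of_carrier": ["Blood to thyroid iodide"]
}
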