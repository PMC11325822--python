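domain,disease_group,disease_name,icd10gm_code,orpha_code
endocrinology,Hyperthyroidism,Clinical hyperthyroidism,E05.9,"ORPHA:181,399"
endocrinology,Hyperthyroidism,Latent hyperthyroidism,E05.9,
endocrinology,Hyperthyroidism,Manifest hyperthyroidism,E05.9,
endocrinology,Hyperthyroidism,Graves' disease,E05.0,"ORPHA:525,731"
endocrinology,Hyperthyroidism,Iatrogenic (therapy induced),E05.8,"ORPHA:576,379"
endocrinology,Hyperthyroidism,Unifocal iatrogenic (therapy-induced),E05.8,
endocrinology,Hyperthyroidism,Autonomy of the thyroid gland: multifocal autonomy of the thyroid gland,E05.8,ORPHA:3143
endocrinology,Hyperthyroidism,Autonomy of the thyroid gland: disseminated autonomy of the thyroid gland,E05.8,
endocrinology,Hyperthyroidism,Thyroiditis de Quervain,E06.1,
endocrinology,Hyperthyroidism,Amiodarone-induced hyperthyroidism type I,E05.8,
endocrinology,Hyperthyroidism,Amiodarone-induced hyperthyroidism type II,E05.8,
endocrinology,Hyperthyroidism,Pituitary thyroid receptor resistance,E05.8,
endocrinology,Hyperthyroidism,TSH-oma,D35.2,ORPHA:424
endocrinology,Hypothyroidism,Clinical hypothyroidism,E03.-,
endocrinology,Hypothyroidism,Aplasia of the thyroid gland,E03.1,
endocrinology,Hypothyroidism,Iatrogenic (therapy-related) drug-induced,E03.2,
endocrinology,Hypothyroidism,Iatrogenic hypothyroidism/condition after surgery,E89.0,
endocrinology,Hypothyroidism,Autoimmune thyroiditis,E06.3,
endocrinology,Hypothyroidism,Secondary & tertiary hypothyroidism,E23.0,
endocrinology,Sarcoidosis,Sarcoidosis,D86.-,
gastroenterology,Viral Hepatitis,Hepatitis A,B15.0,
gastroenterology,Viral Hepatitis,Acute hepatitis B,B16.0,
gastroenterology,Viral Hepatitis,Acute hepatitis C,B17.1,
gastroenterology,Viral Hepatitis,Acute hepatitis E,B17.2,
gastroenterology,Hereditary liver diseases,Hemochromatosis,E83.1,
gastroenterology,Hereditary liver diseases,Wilson's disease,E83.0,
gastroenterology,Hereditary liver diseases,Alpha-1 antitrypsin deficiency in adults,E88.0,
pneumonology,Solid malignancy,Solid malignancy (Bronchial carcinoma),C34.-,
pneumonology,Tuberculosis,Tuberculosis,A15.-,
pneumonology,Sarcoidosis,Sarcoidosis,D86.-,
pneumonology,Viral infections,Influenza,J10.0,
hematology,Cancer,Acute myeloid leukemia (AML),C92.0,"ORPHA:319,465"
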