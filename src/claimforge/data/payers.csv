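hios_id,product_name,payer_type
10207,Medicare Part A Fee-for-Service,MEDICARE
38344,Medicare Advantage Complete HMO,MEDICARE
55290,State Medicaid Managed Care Plus,MEDICAID
61392,Medicaid Fee-for-Service Program,MEDICAID
18581,Anchor Blue Select PPO,COMMERCIAL
27086,Evergreen Health Choice EPO,COMMERCIAL
33653,Pinnacle Gold HMO 2500,COMMERCIAL
49716,Harbor Bronze HDHP 6000,COMMERCIAL
72804,Cascade Silver POS,COMMERCIAL
90115,Keystone Platinum PPO 500,COMMERCIAL
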