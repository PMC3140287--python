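flap_type,index_year,index_cost,comparator_year,comparator_cost,indication
ALT,2005,70045,2005,68667,Chronic lower extremity wound
DIEP,2009,44880,2009,18748,Breast cancer
Fibula,2006,47205,2007,16500,Traumatic facial wound
Latissimus dorsi,2008,103015,2006,17578,Head and neck cancer
Latissimus dorsi,2005,14718,2005,16299,Traumatic lower extremity wound
VRAM,2008,55591,2008,24198,Traumatic lower extremity wound
RFF,2004,50426,2004,30643,Intraoral cancer
RFF,2009,75751,2009,28891,Intraoral cancer
Scapula,2005,44474,2008,29335,Romberg's disease
SGAP,2008,21418,2008,23492,Breast cancer
SGAP,2008,38004,2008,18751,Breast cancer
SIEA,2008,43390,2009,45304,Breast cancer
SIEA,2008,51963,2009,20277,Breast cancer
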