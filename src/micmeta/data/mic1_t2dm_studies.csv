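study_id,n_case,mean_case,sd_case,n_control,mean_control,sd_control,sample_type,substance,country,year,bmi_stratum
GSE20966,10,5.647,3.367,10,2.172,1.655,pancreatic beta cell,mRNA,USA,2010,
GSE12643,10,10.345,0.229,10,10.348,0.408,myotubes,mRNA,Denmark,2008,
GSE13760,10,101.222,9.536,11,95.791,7.878,arterial tissue (intima media),mRNA,Denmark,2011,
GSE16415,5,0.736,0.521,5,0.136,0.098,omentum (visceral tissue),mRNA,India,2009,
GSE23343,10,0.350,0.118,7,0.438,0.240,liver,mRNA,Japan,2010,
GSE25724,6,4.660,0.182,7,4.363,0.242,pancreatic islets,mRNA,Italy,2010,
GSE38642,9,10.000,0.512,54,9.691,0.626,pancreatic islets,mRNA,Sweden,2012,
GSE19420,10,3.424,0.194,12,3.632,0.416,skeletal muscle biopsies,mRNA,Netherlands,2010,
GSE26168,9,8.278,7.719,8,-3.150,12.954,blood,mRNA,Singapore,2010,
GSE9006,12,19.225,17.956,24,15.308,13.606,blood,mRNA,USA,2007,
GSE27951,10,4.542,0.271,12,4.403,0.343,adipose tissue,mRNA,UK,2011,
Castensen,180,537.100,166.440,372,499.700,149.330,blood,protein,Germany,2010,
Hong,75,866.040,628.210,137,484.050,291.000,blood,protein,Korea,2014,
Shin,65,643.290,535.390,42,210.120,211.810,blood,protein,Korea,2016,
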