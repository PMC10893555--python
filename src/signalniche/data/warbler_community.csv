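code,common_name,scientific_name,status,n_individuals,niche_area,overlap_total,overlap_migrant,overlap_breeding
AMRE,American Redstart,Setophaga ruticilla,breeding,24,2.4280,0.5208,0.4093,0.1813
BBWA,Bay-breasted Warbler,Setophaga castanea,migrant,4,0.3191,0.0106,0.0000,0.0106
BAWW,Black-and-white Warbler,Mniotilta varia,migrant,8,0.9182,0.9489,0.6966,0.6294
BLBW,Blackburnian Warbler,Setophaga fusca,migrant,17,5.1158,0.2666,0.2247,0.1017
BLPW,Blackpoll Warbler,Setophaga striata,migrant,6,0.7533,0.1545,0.1545,0.0000
BTBW,Black-throated Blue Warbler,Setophaga caerulescens,migrant,4,0.2627,0.7903,0.6751,0.6862
BTNW,Black-throated Green Warbler,Setophaga virens,breeding,11,1.7176,0.5335,0.5050,0.1678
BWWA,Blue-winged Warbler,Vermivora cyanoptera,breeding,17,0.7984,0.4874,0.1633,0.4835
CAWA,Canada Warbler,Cardellina canadensis,migrant,6,0.2908,0.9717,0.9604,0.9200
CMWA,Cape May Warbler,Setophaga tigrina,migrant,4,0.8590,0.1355,0.1355,0.0000
CERW,Cerulean Warbler,Setophaga cerulea,breeding,12,0.8898,0.9700,0.7161,0.9418
CSWA,Chestnut-sided Warbler,Setophaga pensylvanica,breeding,16,1.4707,0.9533,0.7211,0.9160
COYE,Common Yellowthroat,Geothlypis trichas,breeding,17,1.0724,0.8552,0.5531,0.7103
CONW,Connecticut Warbler,Oporornis agilis,migrant,4,0.3918,0.0098,0.0098,0.0000
GWWA,Golden-winged Warbler,Vermivora chrysoptera,migrant,4,0.2123,0.9522,0.1281,0.9485
HOWA,Hooded Warbler,Setophaga citrina,breeding,14,0.9171,0.4225,0.2619,0.2744
MAWA,Magnolia Warbler,Setophaga magnolia,migrant,20,1.2118,0.8684,0.1629,0.8368
MOWA,Mourning Warbler,Geothlypis philadelphia,migrant,4,0.2566,0.9418,0.0000,0.9418
NAWA,Nashville Warbler,Leiothlypis ruficapilla,migrant,15,1.1557,0.7959,0.7934,0.0255
NOPA,Northern Parula,Setophaga americana,migrant,10,1.3480,0.7852,0.4255,0.4414
NOWA,Northern Waterthrush,Parkesia noveboracensis,migrant,10,0.2920,0.7037,0.3882,0.4020
OVEN,Ovenbird,Seiurus aurocapilla,breeding,13,1.8217,0.0000,0.0000,0.0000
PAWA,Palm Warbler,Setophaga palmarum,migrant,4,0.3148,0.9732,0.8875,0.9708
PIWA,Pine Warbler,Setophaga pinus,breeding,14,1.1094,0.9663,0.5508,0.8728
PRAW,Prairie Warbler,Setophaga discolor,migrant,4,0.0845,0.9573,0.5182,0.9527
PROW,Prothonotary Warbler,Protonotaria citrea,breeding,10,0.6590,0.9274,0.9156,0.3032
TEWA,Tennessee Warbler,Leiothlypis peregrina,migrant,17,3.4065,0.0097,0.0097,0.0000
WIWA,Wilson's Warbler,Cardellina pusilla,migrant,6,0.8118,0.8827,0.6616,0.8576
YEWA,Yellow Warbler,Setophaga petechia,breeding,21,1.3677,0.4812,0.4153,0.3469
YRWA,Yellow-rumped Warbler,Setophaga coronata,migrant,13,0.8131,0.6612,0.1331,0.5511
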