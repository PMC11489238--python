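gene,role
KID001,target
KID002,target
KID003,target
KID004,target
KID005,target
KID006,target
KID007,target
KID008,target
KID009,target
KID010,target
KID011,target
KID012,target
KID013,target
KID014,target
KID015,target
KID016,target
KID017,target
KID018,target
KID019,target
KID020,target
KID021,target
KID022,target
KID023,target
KID024,target
KID025,target
KID026,target
KID027,target
KID028,target
KID029,target
KID030,target
KID031,target
KID032,target
KID033,target
KID034,target
KID035,target
KID036,target
KID037,target
KID038,target
KID039,target
KID040,target
KID041,target
KID042,target
KID043,target
KID044,target
KID045,target
KID046,target
KID047,target
KID048,target
KID049,target
KID050,target
KID051,target
KID052,target
KID053,target
KID054,target
KID055,target
KID056,target
KID057,target
KID058,target
KID059,target
KID060,target
KID061,target
KID062,target
KID063,target
KID064,target
KID065,target
KID066,target
KID067,target
KID068,target
KID069,target
KID070,target
KID071,target
KID072,target
KID073,target
KID074,target
KID075,target
KID076,target
KID077,target
KID078,target
KID079,target
KID080,target
KID081,target
KID082,target
KID083,target
KID084,target
KID085,target
KID086,target
KID087,target
KID088,target
KID089,target
KID090,target
KID091,target
KID092,target
KID093,target
KID094,target
KID095,target
KID096,target
KID097,target
KID098,target
KID099,target
KID100,target
KID101,target
KID102,target
KID103,target
KID104,target
KID105,target
KID106,target
KID107,target
KID108,target
KID109,target
KID110,target
KID111,target
KID112,target
KID113,target
KID114,target
KID115,target
KID116,target
KID117,target
KID118,target
KID119,target
KID120,target
KID121,target
KID122,target
KID123,target
KID124,target
KID125,target
KID126,target
KID127,target
KID128,target
KID129,target
KID130,target
KID131,target
KID132,target
KID133,target
KID134,target
KID135,target
KID136,target
KID137,target
KID138,target
KID139,target
KID140,target
KID141,target
KID142,target
KID143,target
KID144,target
KID145,target
KID146,target
KID147,target
KID148,target
KID149,target
KID150,target
KID151,target
KID152,target
KID153,target
KID154,target
KID155,target
KID156,target
KID157,target
KID158,target
KID159,target
KID160,target
KID161,target
KID162,target
KID163,target
KID164,target
KID165,target
KID166,target
KID167,target
KID168,target
KID169,target
KID170,target
KID171,target
KID172,target
KID173,target
KID174,target
KID175,target
KID176,target
KID177,target
KID178,target
KID179,target
KID180,target
KID181,target
KID182,target
KID183,target
KID184,target
KID185,target
KID186,target
KID187,target
KID188,target
KID189,target
KID190,target
KID191,target
KID192,target
KID193,target
KID194,target
KID195,target
KID196,target
KID197,target
KID198,target
KID199,target
KID200,target
KID201,target
KID202,target
KID203,target
KID204,target
KID205,target
KID206,target
KID207,target
KID208,target
KID209,target
KID210,target
KID211,target
KID212,target
KID213,target
KID214,target
KID215,target
KID216,target
KID217,target
KID218,target
KID219,target
KID220,target
KID221,target
KID222,target
KID223,target
KID224,target
KID225,target
KID226,target
KID227,target
KID228,target
KID229,target
KID230,target
KID231,target
KID232,target
KID233,target
KID234,target
KID235,target
KID236,target
KID237,target
KID238,target
KID239,target
KID240,target
KID241,target
KID242,target
KID243,target
KID244,target
KID245,target
KID246,target
KID247,target
KID248,target
KID249,target
KID250,target
KID251,target
KID252,target
KID253,target
KID254,target
KID255,target
KID256,target
KID257,target
KID258,target
KID259,target
KID260,target
KID261,target
KID262,target
KID263,target
KID264,target
KID265,target
KID266,target
KID267,target
KID268,target
KID269,target
KID270,target
KID271,target
KID272,target
KID273,target
KID274,target
KID275,target
KID276,target
KID277,target
KID278,target
KID279,target
KID280,target
KID281,target
KID282,target
KID283,target
KID284,target
KID285,target
KID286,target
KID287,target
KID288,target
KID289,target
KID290,target
KID291,target
KID292,target
KID293,target
KID294,target
KID295,target
KID296,target
KID297,target
KID298,target
KID299,target
KID300,target
KID301,target
KID302,target
KID303,target
KID304,target
KID305,target
KID306,target
KID307,target
KID308,target
KID309,target
KID310,target
KID311,target
KID312,target
KID313,target
KID314,target
KID315,target
KID316,target
KID317,target
KID318,target
KID319,target
KID320,target
KID321,target
KID322,target
KID323,target
KID324,target
KID325,target
KID326,target
KID327,target
KID328,target
KID329,target
KID330,target
KID331,target
KID332,target
KID333,target
KID334,target
KID335,target
KID336,target
KID337,target
KID338,target
KID339,target
KID340,target
KID341,target
KID342,target
KID343,target
KID344,target
KID345,target
KID346,target
KID347,target
KID348,target
KID349,target
KID350,target
KID351,target
KID352,target
KID353,target
KID354,target
KID355,target
KID356,target
KID357,target
KID358,target
KID359,target
KID360,target
KID361,target
KID362,target
KID363,target
KID364,target
KID365,target
KID366,target
KID367,target
KID368,target
KID369,target
KID370,target
ACTB,housekeeping
B2M,housekeeping
GAPDH,housekeeping
HPRT1,housekeeping
RPLP0,housekeeping
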